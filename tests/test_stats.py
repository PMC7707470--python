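"""Cohort statistics: CoV, repeatability cascade, paired comparisons with an
exhaustive signed-rank oracle, and regressions."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from musclemetrics import (
    CohortSpec,
    CohortTable,
    add_params_to_cohort,
    apply_repeatability_gate,
    between_subject_cov,
    compare_fmax_methods,
    cov,
    limb_comparison,
    make_cohort,
    percent_diff_limbs,
    regress_vtot,
    repeatability_gate,
    retained_muscles,
)
from musclemetrics.io import QUANTITY_UNITS
from musclemetrics.stats import StatsError


class TestCov:
    def test_zero_dispersion(self):
        assert cov([5, 5, 5]) == 0.0

    def test_two_value_hand_case(self):
        # SD = |8-12|/sqrt(2) = 2.8284..., mean = 10
        assert cov([8, 12]) == pytest.approx(100 * np.sqrt(8) / 10, abs=1e-12)

    @pytest.mark.parametrize("c", [0.1, 3.0, 1e4])
    def test_scale_invariance(self, c):
        x = np.array([3.0, 7.0, 11.0, 4.0])
        assert cov(c * x) == pytest.approx(cov(x))

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            cov([5.0])
        with pytest.raises(StatsError):
            cov([-3.0, 1.0])


class TestRepeatabilityGate:
    @pytest.mark.parametrize(
        "inter, intra, verdict",
        [
            (4.2, None, "accepted_no_intra_test"),   # Vastus medialis
            (49.4, 7.6, "accepted_after_intra"),     # Peroneus brevis
            (48.2, 10.9, "discarded"),               # Peroneus longus
            (14.6, 21.6, "discarded"),               # Gluteus minimus
            (5.0, None, "accepted_no_intra_test"),   # boundary: 5% is acceptable
        ],
    )
    def test_cascade(self, inter, intra, verdict):
        assert repeatability_gate(inter, intra) == verdict

    def test_missing_intra_study_demanded(self):
        with pytest.raises(StatsError, match="intra-operator"):
            repeatability_gate(7.0, None)

    def test_published_table_yields_23_retained(self):
        gated = apply_repeatability_gate()
        assert len(gated) == 25
        discarded = set(gated.loc[gated.verdict == "discarded", "muscle"])
        assert discarded == {"Gluteus minimus", "Peroneus longus"}
        assert len(retained_muscles()) == 23


class TestPercentDiff:
    def test_equal_sides_zero(self):
        assert percent_diff_limbs(7.0, 7.0) == 0.0

    @pytest.mark.parametrize("r, l", [(120.0, 100.0), (50.0, 80.0), (3.0, 2.9)])
    def test_sign_follows_right_minus_left(self, r, l):
        assert np.sign(percent_diff_limbs(r, l)) == np.sign(r - l)

    def test_right_denominator_convention(self):
        assert percent_diff_limbs(120.0, 100.0, "right") == pytest.approx(100 * 20 / 120)
        assert percent_diff_limbs(120.0, 100.0, "left") == pytest.approx(20.0)

    def test_swap_flips_sign_with_swapped_convention(self):
        a = percent_diff_limbs(120.0, 100.0, "right")
        b = percent_diff_limbs(100.0, 120.0, "left")
        assert a == pytest.approx(-b)


def _bilateral_table(right, left, muscle="M1"):
    rows = []
    for i, (r, l) in enumerate(zip(right, left)):
        rows.append((f"S{i:02d}", "right", muscle, "volume", r, "cm3"))
        rows.append((f"S{i:02d}", "left", muscle, "volume", l, "cm3"))
    return CohortTable(
        pd.DataFrame(rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"])
    )


class TestLimbComparison:
    def test_identical_sides_degenerate(self):
        right = np.linspace(50, 150, 8)
        res = limb_comparison(_bilateral_table(right, right), "volume")["M1"]
        assert res.test == "degenerate_no_difference"
        assert res.p_value == 1.0
        np.testing.assert_allclose(res.diffs_pct, 0.0)

    def test_consistent_20pct_shrinkage_significant_at_n11(self):
        rng = np.random.default_rng(5)
        right = rng.lognormal(4.0, 0.4, size=11) + 20
        res = limb_comparison(_bilateral_table(right, 0.8 * right), "volume")["M1"]
        assert res.p_value < 0.05
        np.testing.assert_allclose(res.diffs_pct, 20.0, atol=1e-9)
        # all-equal signs at n=11 under the exact signed-rank null
        assert sps.wilcoxon(right, 0.8 * right, method="exact").pvalue == pytest.approx(
            2 / 2**11
        )

    def test_incomplete_pairs_excluded(self):
        right = np.array([100.0, 110.0, 120.0])
        table = _bilateral_table(right, 0.9 * right)
        # drop one left record
        recs = table.records.drop(table.records.index[-1])
        res = limb_comparison(CohortTable(recs), "volume")["M1"]
        assert res.n_pairs == 2


class TestWilcoxonOracle:
    """The signed-rank p used by the pipeline equals exhaustive enumeration
    over all 2^n sign assignments."""

    @staticmethod
    def _enumerated_pvalue(d):
        ranks = sps.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        ws = np.array(
            [sum(r for s, r in zip(signs, ranks) if s) for signs in product((0, 1), repeat=len(d))]
        )
        return min(1.0, 2 * min((ws <= w_plus).mean(), (ws >= w_plus).mean()))

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.standard_normal(n) * 2 + 0.4
        expected = self._enumerated_pvalue(d)
        assert sps.wilcoxon(d, method="exact").pvalue == pytest.approx(expected, abs=1e-12)


class TestBetweenSubjectCov:
    def test_zero_cov_cohort(self):
        tbl = pd.DataFrame(
            {"muscle": ["M1"], "mean_volume_cm3": [80.0], "cov_volume_pct": [0.0],
             "mean_length_cm": [25.0]}
        )
        spec = CohortSpec(n_subjects=5, muscle_table=tbl, limb_diff_sd_pct=0.0, rng_seed=0)
        out = between_subject_cov(make_cohort(spec), "volume")
        np.testing.assert_allclose(out["cov_pct"], 0.0, atol=1e-9)

    def test_recovers_generator_cov(self):
        tbl = pd.DataFrame(
            {"muscle": ["M1"], "mean_volume_cm3": [100.0], "cov_volume_pct": [20.0],
             "mean_length_cm": [30.0]}
        )
        spec = CohortSpec(n_subjects=200, muscle_table=tbl, rng_seed=3)
        out = between_subject_cov(make_cohort(spec), "volume")
        right = out.loc[out.side == "right", "cov_pct"].item()
        assert right == pytest.approx(20.0, abs=3.0)


class TestCompareFmaxMethods:
    @staticmethod
    def _force_table(ratio):
        rows = []
        for i in range(6):
            vls = 100.0 + 10 * i
            for side in ("right", "left"):
                rows.append((f"S{i}", side, "M1", "fmax_vls", vls * ratio, "N"))
                rows.append((f"S{i}", side, "M1", "fmax_llms", vls, "N"))
        return CohortTable(
            pd.DataFrame(rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"])
        )

    def test_equal_methods_no_difference(self):
        res = compare_fmax_methods(self._force_table(1.0))["M1"]
        np.testing.assert_allclose(res.diffs_pct, 0.0)
        assert res.p_value == 1.0

    def test_denominator_conventions(self):
        half = self._force_table(0.5)
        assert compare_fmax_methods(half, denominator="llms")["M1"].diffs_pct[0] == pytest.approx(-50.0)
        assert compare_fmax_methods(half, denominator="vls")["M1"].diffs_pct[0] == pytest.approx(-100.0)

    def test_bundled_and_total_agree_for_simple_muscles(self):
        cohort = make_cohort(CohortSpec(n_subjects=4, rng_seed=8))
        bundled = compare_fmax_methods(add_params_to_cohort(cohort))
        total = compare_fmax_methods(add_params_to_cohort(cohort, bundle_granularity=False))
        assert bundled["Soleus"].diffs_pct == pytest.approx(total["Soleus"].diffs_pct)


class TestRegression:
    @staticmethod
    def _cohort_with_mass(vtot_fn, n=10):
        rows, mass = [], []
        for i in range(n):
            m = 55.0 + 3.0 * i
            mass.append(m)
            rows.append((f"S{i:02d}", "right", "M1", "volume", vtot_fn(m), "cm3"))
        anth = pd.DataFrame({"subject_id": [f"S{i:02d}" for i in range(n)], "body_mass_kg": mass})
        return CohortTable(
            pd.DataFrame(rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"]),
            anth,
        )

    def test_exact_linear_data_r2_one(self):
        cohort = self._cohort_with_mass(lambda m: 30.0 * m + 5.0)
        res = regress_vtot(cohort, "body_mass_kg")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(30.0)

    def test_r2_equals_squared_correlation(self):
        rng = np.random.default_rng(2)
        cohort = self._cohort_with_mass(lambda m: 20 * m + 100 * rng.standard_normal())
        res = regress_vtot(cohort, "body_mass_kg")
        vt = cohort.records["value"].to_numpy()
        x = cohort.anthropometrics["body_mass_kg"].to_numpy()
        assert res.r_squared == pytest.approx(np.corrcoef(x, vt)[0, 1] ** 2, abs=1e-12)

    def test_independent_predictor_r2_near_zero(self):
        rng = np.random.default_rng(4)
        cohort = self._cohort_with_mass(lambda m: 2000 + 100 * rng.standard_normal(), n=200)
        assert regress_vtot(cohort, "body_mass_kg").r_squared < 0.05

    def test_zero_variance_predictor_rejected(self):
        cohort = self._cohort_with_mass(lambda m: 30 * m)
        cohort.anthropometrics["body_mass_kg"] = 60.0
        with pytest.raises(StatsError, match="variance"):
            regress_vtot(cohort, "body_mass_kg")


def test_asymmetric_cohort_recovers_injected_asymmetry():
    tbl = pd.DataFrame(
        {"muscle": ["M1"], "mean_volume_cm3": [100.0], "cov_volume_pct": [20.0],
         "mean_length_cm": [30.0]}
    )
    spec = CohortSpec(
        n_subjects=200, muscle_table=tbl,
        limb_diff_mean_pct=-10.0, limb_diff_sd_pct=5.0, rng_seed=9,
    )
    res = limb_comparison(make_cohort(spec), "volume")["M1"]
    se = 5.0 / np.sqrt(200)
    assert res.diffs_pct.mean() == pytest.approx(-10.0, abs=3 * se)
    assert res.p_value < 1e-6
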