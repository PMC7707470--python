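"""Cohort statistics: repeatability gating, bilateral comparisons,
between-subject variability, method comparison and anthropometric
regressions.

The repeatability gate is a two-stage cascade on segmentation-repeat
coefficients of variation (CoV = 100 * SD / mean, n-1 SD): muscles with
inter-operator CoV <= 5% are accepted outright; those above 5% require an
intra-operator repeat study and are kept only if its CoV stays <= 10%.

Paired comparisons (right vs left limb, and VLS vs LLMS forces) test the
per-subject differences for normality with a one-sample Kolmogorov-Smirnov
test (sample-estimated mean/SD; Lilliefors correction optional) and then use
a paired t test or, for non-normal data, the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable

ALPHA = 0.05
INTER_OP_THRESHOLD_PCT = 5.0
ACCEPTABLE_COV_PCT = 10.0

VERDICTS = ("accepted_no_intra_test", "accepted_after_intra", "discarded")


class StatsError(ValueError):
    pass


def cov(values) -> float:
    """Coefficient of variation in percent: 100 * sample SD (n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("CoV needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise StatsError("CoV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def repeatability_gate(inter_cov_pct: float, intra_cov_pct: float | None = None) -> str:
    """Two-stage acceptance cascade on segmentation repeatability CoVs."""
    if inter_cov_pct < 0 or (intra_cov_pct is not None and intra_cov_pct < 0):
        raise StatsError("CoVs must be non-negative")
    if inter_cov_pct <= INTER_OP_THRESHOLD_PCT:
        return "accepted_no_intra_test"
    if intra_cov_pct is None:
        raise StatsError(
            f"inter-operator CoV {inter_cov_pct}% exceeds {INTER_OP_THRESHOLD_PCT}%: "
            "an intra-operator repeatability study is required"
        )
    if intra_cov_pct <= ACCEPTABLE_COV_PCT:
        return "accepted_after_intra"
    return "discarded"


def default_repeatability_table() -> pd.DataFrame:
    """The study's per-muscle inter/intra-operator segmentation CoVs."""
    with resources.files("musclemetrics.data").joinpath(
        "segmentation_repeatability.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def apply_repeatability_gate(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply the gate row-wise; returns the table with a ``verdict`` column."""
    table = default_repeatability_table() if table is None else table.copy()
    verdicts = []
    for r in table.itertuples():
        intra = getattr(r, "intra_op_cov_pct", None)
        intra = None if intra is None or pd.isna(intra) else float(intra)
        verdicts.append(repeatability_gate(float(r.inter_op_cov_pct), intra))
    table["verdict"] = verdicts
    return table


def retained_muscles(table: pd.DataFrame | None = None) -> list[str]:
    gated = apply_repeatability_gate(table)
    return list(gated.loc[gated["verdict"] != "discarded", "muscle"])


def percent_diff(a: float, b: float, denominator: str = "first") -> float:
    """Signed percentage difference between two positive values.

    ``denominator`` selects the reference: "first" -> (a-b)/a, "second" ->
    (a-b)/b, "mean" -> (a-b)/mean(a,b); the sign always follows a - b.
    """
    if a <= 0 or b <= 0:
        raise StatsError("percentage difference needs positive values")
    denom = {"first": a, "second": b, "mean": 0.5 * (a + b)}[denominator]
    return float(100.0 * (a - b) / denom)


def percent_diff_limbs(right: float, left: float, denominator: str = "right") -> float:
    """Signed right-vs-left difference, positive iff the right side is larger.

    Default convention: (right - left) / right * 100."""
    mapping = {"right": "first", "left": "second", "mean": "mean"}
    return percent_diff(right, left, mapping[denominator])


def normality_pvalue(x, lilliefors: bool = False) -> float:
    """One-sample KS test against a normal with sample-estimated mean/SD.

    With ``lilliefors=True`` the estimated-parameter correction is applied
    (via statsmodels) instead of the plain KS distribution.
    """
    x = np.asarray(x, dtype=float)
    if x.std(ddof=1) == 0:
        return 0.0  # degenerate: no spread, treat as non-normal
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    return float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


@dataclass
class ComparisonResult:
    muscle: str
    quantity: str
    n_pairs: int
    diffs_pct: np.ndarray  # per-subject signed percentage differences
    min_diff_pct: float
    max_diff_pct: float
    test: str  # paired_t | wilcoxon_signed_rank | degenerate_no_difference
    p_value: float
    normality_p: float
    median_a: float
    median_b: float


def _paired_test(a: np.ndarray, b: np.ndarray, alpha: float, lilliefors: bool):
    d = a - b
    if np.allclose(d, 0):
        return "degenerate_no_difference", 1.0, 0.0
    norm_p = normality_pvalue(d, lilliefors)
    if norm_p > alpha:
        res = sps.ttest_rel(a, b)
        return "paired_t", float(res.pvalue), norm_p
    res = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return "wilcoxon_signed_rank", float(res.pvalue), norm_p


def _compare_paired(
    pivot: pd.DataFrame,
    col_a: str,
    col_b: str,
    quantity: str,
    denominator: str,
    alpha: float,
    lilliefors: bool,
) -> dict[str, ComparisonResult]:
    out: dict[str, ComparisonResult] = {}
    for muscle, grp in pivot.groupby(level="muscle"):
        grp = grp.dropna(subset=[col_a, col_b])  # pairwise exclusion
        if len(grp) < 2:
            continue
        a = grp[col_a].to_numpy()
        b = grp[col_b].to_numpy()
        diffs = np.array(
            [percent_diff(ai, bi, denominator) for ai, bi in zip(a, b)]
        )
        test, p, norm_p = _paired_test(a, b, alpha, lilliefors)
        out[muscle] = ComparisonResult(
            muscle=muscle,
            quantity=quantity,
            n_pairs=len(grp),
            diffs_pct=diffs,
            min_diff_pct=float(diffs.min()),
            max_diff_pct=float(diffs.max()),
            test=test,
            p_value=p,
            normality_p=norm_p,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
        )
    return out


def limb_comparison(
    cohort: CohortTable,
    quantity: str,
    denominator: str = "right",
    alpha: float = ALPHA,
    lilliefors: bool = False,
) -> dict[str, ComparisonResult]:
    """Right-vs-left paired comparison per muscle for one quantity.

    Differences are signed percentages, positive iff the right limb value is
    larger; subjects missing a side are excluded pairwise; muscles with fewer
    than 2 complete pairs are skipped.
    """
    pivot = cohort.pivot_sides(quantity)
    if not {"right", "left"} <= set(pivot.columns):
        raise StatsError(f"quantity {quantity!r} lacks bilateral records")
    pivot = pivot.reset_index().set_index(["subject_id", "muscle"])
    denom = {"right": "first", "left": "second", "mean": "mean"}[denominator]
    return _compare_paired(pivot, "right", "left", quantity, denom, alpha, lilliefors)


def between_subject_cov(
    cohort: CohortTable, quantity: str, pooled: bool = False
) -> pd.DataFrame:
    """CoV across subjects per muscle; per side by default, pooled optional.

    Returns a DataFrame with columns muscle, side, cov_pct (side = "pooled"
    when pooling both limbs' values into one sample)."""
    sub = cohort.records[cohort.records["quantity"] == quantity]
    rows = []
    if pooled:
        for muscle, grp in sub.groupby("muscle"):
            if len(grp) >= 2:
                rows.append((muscle, "pooled", cov(grp["value"])))
    else:
        for (muscle, side), grp in sub.groupby(["muscle", "side"]):
            if len(grp) >= 2:
                rows.append((muscle, side, cov(grp["value"])))
    return pd.DataFrame(rows, columns=["muscle", "side", "cov_pct"])


def compare_fmax_methods(
    cohort: CohortTable,
    denominator: str = "llms",
    alpha: float = ALPHA,
    lilliefors: bool = False,
    side: str | None = None,
) -> dict[str, ComparisonResult]:
    """VLS-vs-LLMS paired force comparison per muscle (or bundle).

    Differences are positive iff the geometry-based (VLS) force is larger.
    Default convention: (VLS - LLMS) / LLMS * 100.  Pairs both sides of every
    subject unless ``side`` restricts to one limb.
    """
    recs = cohort.records
    if side is not None:
        recs = recs[recs["side"] == side]
    vls = recs[recs["quantity"] == "fmax_vls"]
    llms = recs[recs["quantity"] == "fmax_llms"]
    merged = vls.merge(
        llms, on=["subject_id", "side", "muscle"], suffixes=("_vls", "_llms")
    )
    if merged.empty:
        raise StatsError("no paired VLS/LLMS force records")
    merged = merged.set_index(["subject_id", "side", "muscle"])
    denom = {"vls": "first", "llms": "second", "mean": "mean"}[denominator]
    return _compare_paired(
        merged, "value_vls", "value_llms", "fmax", denom, alpha, lilliefors
    )


@dataclass
class RegressionResult:
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def total_muscle_volume(cohort: CohortTable, muscles: list[str] | None = None) -> pd.Series:
    """Per-subject total segmented muscle volume (both limbs, cm3)."""
    sub = cohort.records[cohort.records["quantity"] == "volume"]
    if muscles is not None:
        sub = sub[sub["muscle"].isin(muscles)]
    return sub.groupby("subject_id")["value"].sum()


def regress_vtot(
    cohort: CohortTable,
    predictor: str,
    muscles: list[str] | None = None,
) -> RegressionResult:
    """OLS of total muscle volume against an anthropometric predictor.

    ``predictor`` is one of body_mass_kg, height_cm, limb_mass_kg, bmi (any
    numeric anthropometrics column works).  V_TOT sums the volumes of the
    given muscles (default: all present) over both limbs per subject.
    """
    if cohort.anthropometrics is None or predictor not in cohort.anthropometrics:
        raise StatsError(f"anthropometrics lack predictor {predictor!r}")
    vtot = total_muscle_volume(cohort, muscles)
    x = cohort.anthropometrics.loc[vtot.index, predictor].astype(float)
    if len(vtot) < 3:
        raise StatsError("regression needs at least 3 subjects")
    if np.ptp(x.to_numpy()) == 0:
        raise StatsError(f"predictor {predictor!r} has zero variance")
    res = sps.linregress(x.to_numpy(), vtot.to_numpy())
    return RegressionResult(
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(vtot),
    )


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment across a family of per-muscle tests."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj


def comparisons_to_frame(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "muscle": r.muscle,
            "quantity": r.quantity,
            "n_pairs": r.n_pairs,
            "min_diff_pct": r.min_diff_pct,
            "max_diff_pct": r.max_diff_pct,
            "test": r.test,
            "p_value": r.p_value,
            "normality_p": r.normality_p,
            "median_a": r.median_a,
            "median_b": r.median_b,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows).sort_values("muscle").reset_index(drop=True)
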