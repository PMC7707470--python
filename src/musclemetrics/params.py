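"""PCSA and maximal isometric force under two scaling approaches.

Volume-and-length-based scaling (VLS) personalises force from the imaged
geometry:

    PCSA = V_M / lf0 = V_M / (k * l_M)        [cm2]
    F_max = sigma * PCSA                      [N]

with k the literature ratio of optimal fibre length to muscle length and
sigma the specific tension (default 61 N/cm2, an elderly-population value).

Lower-limb-mass-based scaling (LLMS) instead scales each generic-model
actuator linearly by the subject's lower-limb mass:

    F_max = m_LL / m_LLGen * F_maxGen         [N]

Broad muscles modelled as three actuators (the Glutei and the Adductor
magnus) are compared at bundle granularity: one third of a muscle's total
VLS force is attributed to each bundle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io import QUANTITY_UNITS, CohortTable

DEFAULT_SIGMA_N_CM2 = 61.0
#: lower-limb mass of the generic gait model (both limbs, kg)
DEFAULT_GENERIC_LIMB_MASS_KG = 29.15


class ParamsError(ValueError):
    pass


def _read_data_csv(name: str) -> pd.DataFrame:
    with resources.files("musclemetrics.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass
class ReferenceTables:
    """Literature constants backing the force calculations.

    ``k``: optimal-fibre-length/muscle-length ratio per muscle (0 < k <= 1);
    ``sigma_n_cm2``: specific tension; ``generic_fmax``: DataFrame with
    columns muscle, bundle, fmax_gen_n; ``m_ll_gen_kg``: generic-model
    lower-limb mass; ``limb_mass_convention``: whether m_LL entering the
    scaling is the mass of both limbs or of one limb doubled.
    """

    k: dict[str, float] = field(default_factory=dict)
    sigma_n_cm2: float = DEFAULT_SIGMA_N_CM2
    generic_fmax: pd.DataFrame = field(default_factory=pd.DataFrame)
    m_ll_gen_kg: float = DEFAULT_GENERIC_LIMB_MASS_KG
    limb_mass_convention: str = "both_limbs"  # or "per_limb"

    def __post_init__(self) -> None:
        for muscle, k in self.k.items():
            if not 0 < k:
                raise ParamsError(f"k for {muscle} must be positive, got {k}")
            if k > 1:
                warnings.warn(
                    f"k for {muscle} is {k} > 1 (optimal fibre longer than muscle)",
                    stacklevel=2,
                )
        if self.sigma_n_cm2 <= 0:
            raise ParamsError("sigma must be positive")
        if self.m_ll_gen_kg <= 0:
            raise ParamsError("generic lower-limb mass must be positive")

    @classmethod
    def default(cls, **overrides) -> "ReferenceTables":
        kdf = _read_data_csv("k_ratios.csv")
        gdf = _read_data_csv("generic_model.csv")
        args = dict(
            k=dict(zip(kdf["muscle"], kdf["k"])),
            generic_fmax=gdf,
        )
        args.update(overrides)
        return cls(**args)

    @classmethod
    def from_files(
        cls,
        k_ratios_csv,
        generic_model_csv,
        sigma_n_cm2: float = DEFAULT_SIGMA_N_CM2,
        m_ll_gen_kg: float = DEFAULT_GENERIC_LIMB_MASS_KG,
        limb_mass_convention: str = "both_limbs",
    ) -> "ReferenceTables":
        kdf = pd.read_csv(k_ratios_csv)
        gdf = pd.read_csv(generic_model_csv)
        return cls(
            k=dict(zip(kdf["muscle"], kdf["k"])),
            sigma_n_cm2=sigma_n_cm2,
            generic_fmax=gdf,
            m_ll_gen_kg=m_ll_gen_kg,
            limb_mass_convention=limb_mass_convention,
        )

    def bundles(self, muscle: str) -> list[str]:
        sub = self.generic_fmax[self.generic_fmax["muscle"] == muscle]
        if sub.empty:
            raise ParamsError(f"muscle {muscle!r} absent from the generic model table")
        return list(sub["bundle"])

    def bundle_map(self) -> dict[str, list[str]]:
        return {
            m: list(g["bundle"])
            for m, g in self.generic_fmax.groupby("muscle", sort=False)
            if len(g) > 1
        }


def compute_pcsa(volume_cm3: float, length_cm: float, k: float) -> float:
    """Physiological cross-sectional area, cm2: V_M / (k * l_M)."""
    if volume_cm3 <= 0 or length_cm <= 0 or k <= 0:
        raise ParamsError("volume, length and k must all be positive")
    if k > 1:
        warnings.warn(f"k={k} exceeds 1; optimal fibre length longer than muscle", stacklevel=2)
    return volume_cm3 / (k * length_cm)


def fmax_vls(pcsa_cm2: float, sigma_n_cm2: float = DEFAULT_SIGMA_N_CM2) -> float:
    """Maximal isometric force from geometry: sigma * PCSA, exactly."""
    if pcsa_cm2 <= 0 or sigma_n_cm2 <= 0:
        raise ParamsError("PCSA and sigma must be positive")
    return sigma_n_cm2 * pcsa_cm2


def fmax_llms(m_ll_kg: float, ref: ReferenceTables, muscle: str) -> dict[str, float]:
    """Per-bundle generic forces scaled by m_LL / m_LLGen."""
    if m_ll_kg <= 0:
        raise ParamsError("lower-limb mass must be positive")
    sub = ref.generic_fmax[ref.generic_fmax["muscle"] == muscle]
    if sub.empty:
        raise ParamsError(f"no generic F_max for muscle {muscle!r}")
    scale = m_ll_kg / ref.m_ll_gen_kg
    return {str(r.bundle): scale * float(r.fmax_gen_n) for r in sub.itertuples()}


def split_bundles(
    fmax_total_n: float, muscle: str, ref: ReferenceTables
) -> dict[str, float]:
    """Attribute one third of the total force to each of a muscle's three
    bundles; non-bundled muscles pass through unchanged."""
    bmap = ref.bundle_map()
    if muscle not in bmap:
        return {muscle: fmax_total_n}
    bundles = bmap[muscle]
    return {b: fmax_total_n / len(bundles) for b in bundles}


def add_params_to_cohort(
    cohort: CohortTable,
    ref: ReferenceTables | None = None,
    bundle_granularity: bool = True,
) -> CohortTable:
    """Append PCSA, VLS and LLMS force records to a cohort of volumes/lengths.

    Requires paired volume and length records per (subject, side, muscle).
    LLMS needs a ``limb_mass_kg`` column in the anthropometrics; when the
    reference convention is ``per_limb`` that mass is doubled before scaling
    against the generic model's bilateral lower-limb mass.  Muscles without a
    k ratio are left without PCSA/force records (reported, never defaulted).
    """
    ref = ref or ReferenceTables.default()
    vol = cohort.records[cohort.records["quantity"] == "volume"]
    length = cohort.records[cohort.records["quantity"] == "length"]
    merged = vol.merge(
        length,
        on=["subject_id", "side", "muscle"],
        suffixes=("_v", "_l"),
    )
    missing_k = sorted(set(merged["muscle"]) - set(ref.k))
    if missing_k:
        warnings.warn(
            f"no k ratio for {missing_k}; PCSA/F_max unavailable for these muscles",
            stacklevel=2,
        )
    limb_mass = None
    if cohort.anthropometrics is not None and "limb_mass_kg" in cohort.anthropometrics:
        limb_mass = cohort.anthropometrics["limb_mass_kg"]

    rows = []
    for r in merged.itertuples():
        if r.muscle not in ref.k:
            continue
        pcsa = compute_pcsa(r.value_v, r.value_l, ref.k[r.muscle])
        total = fmax_vls(pcsa, ref.sigma_n_cm2)
        rows.append((r.subject_id, r.side, r.muscle, "pcsa", pcsa, QUANTITY_UNITS["pcsa"]))
        if bundle_granularity:
            for bundle, f in split_bundles(total, r.muscle, ref).items():
                rows.append(
                    (r.subject_id, r.side, bundle, "fmax_vls", f, QUANTITY_UNITS["fmax_vls"])
                )
        else:
            rows.append(
                (r.subject_id, r.side, r.muscle, "fmax_vls", total, QUANTITY_UNITS["fmax_vls"])
            )
        if limb_mass is not None and r.subject_id in limb_mass.index:
            m_ll = float(limb_mass.loc[r.subject_id])
            if ref.limb_mass_convention == "per_limb":
                m_ll *= 2.0
            try:
                per_bundle = fmax_llms(m_ll, ref, r.muscle)
            except ParamsError:
                continue
            if bundle_granularity:
                for bundle, f in per_bundle.items():
                    rows.append(
                        (r.subject_id, r.side, bundle, "fmax_llms", f, QUANTITY_UNITS["fmax_llms"])
                    )
            else:
                rows.append(
                    (
                        r.subject_id,
                        r.side,
                        r.muscle,
                        "fmax_llms",
                        sum(per_bundle.values()),
                        QUANTITY_UNITS["fmax_llms"],
                    )
                )
    new = pd.DataFrame(
        rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"]
    ).drop_duplicates(subset=["subject_id", "side", "muscle", "quantity"])
    return cohort.with_records(new)
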