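"""End-to-end orchestration: volumes -> geometry -> parameters -> statistics.

Every stage reads and writes the long-format cohort CSV, so a run can enter
at any point: with label volumes, with a volumes+lengths table, or with a
fully parameterised table.  Outputs are deterministic given the config and
seed, and every CSV carries a provenance comment header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .geometry import DEFAULT_TISSUE_DENSITY, muscle_geometry
from .io import (
    QUANTITY_UNITS,
    CohortTable,
    read_cohort_csv,
    read_label_volume,
    write_anthropometrics_csv,
    write_cohort_csv,
)
from .params import ReferenceTables, add_params_to_cohort
from .phantoms import CohortSpec, make_cohort
from .stats import (
    ALPHA,
    apply_repeatability_gate,
    between_subject_cov,
    compare_fmax_methods,
    comparisons_to_frame,
    limb_comparison,
    regress_vtot,
    retained_muscles,
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path = Path("musclemetrics_out")
    seed: int = 0
    # input: exactly one of synth / volumes_dir / cohort_csv drives stage 1
    synth: dict | None = None
    volumes_dir: Path | None = None
    label_map_csv: Path | None = None
    cohort_csv: Path | None = None
    anthropometrics_csv: Path | None = None
    smoothing_spans: dict[str, int] = field(default_factory=dict)
    density_g_cm3: float = DEFAULT_TISSUE_DENSITY
    sigma_n_cm2: float = 61.0
    k_ratios_csv: Path | None = None
    generic_model_csv: Path | None = None
    m_ll_gen_kg: float | None = None
    limb_mass_convention: str = "both_limbs"
    limb_diff_denominator: str = "right"
    fmax_diff_denominator: str = "llms"
    alpha: float = ALPHA
    lilliefors: bool = False
    repeatability_csv: Path | None = None
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("volumes_dir", "label_map_csv", "cohort_csv", "anthropometrics_csv",
                     "k_ratios_csv", "generic_model_csv", "repeatability_csv"):
            val = getattr(cfg, name)
            if val is not None:
                p = Path(val)
                if not p.exists():
                    raise ConfigError(f"{name} does not exist: {p}")
                setattr(cfg, name, p)
        cfg.out_dir = Path(cfg.out_dir)
        if not 0 < cfg.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        return cfg

    def digest(self) -> str:
        # output location is not part of the scientific configuration
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"musclemetrics {__version__} config={self.digest()}"


def reference_tables(config: RunConfig) -> ReferenceTables:
    overrides = {
        "sigma_n_cm2": config.sigma_n_cm2,
        "limb_mass_convention": config.limb_mass_convention,
    }
    if config.m_ll_gen_kg is not None:
        overrides["m_ll_gen_kg"] = config.m_ll_gen_kg
    if config.k_ratios_csv or config.generic_model_csv:
        if not (config.k_ratios_csv and config.generic_model_csv):
            raise ConfigError("k_ratios_csv and generic_model_csv go together")
        return ReferenceTables.from_files(
            config.k_ratios_csv, config.generic_model_csv, **overrides
        )
    return ReferenceTables.default(**overrides)


def geometry_stage(config: RunConfig) -> CohortTable:
    """Measure volume and centreline length for every label of every volume
    file under ``volumes_dir`` (filenames: <subject_id>.nii/.nii.gz/.mha)."""
    if config.volumes_dir is None:
        raise ConfigError("geometry stage needs volumes_dir")
    files = sorted(
        p for p in Path(config.volumes_dir).iterdir()
        if "".join(p.suffixes) in (".nii", ".nii.gz", ".mha", ".mhd")
    )
    if not files:
        raise ConfigError(f"no label volumes found in {config.volumes_dir}")
    rows = []
    for path in files:
        subject = path.name.split(".")[0]
        vol = read_label_volume(path, config.label_map_csv)
        for label in vol.labels_present():
            muscle, side = vol.label_map.get(label, (f"label_{label}", "right"))
            span = config.smoothing_spans.get(muscle)
            try:
                geo = muscle_geometry(vol, label, span)
            except Exception as exc:
                raise RuntimeError(
                    f"geometry failed for subject {subject}, muscle {muscle} ({side}): {exc}"
                ) from exc
            rows.append((subject, side, muscle, "volume", geo.volume_cm3,
                         QUANTITY_UNITS["volume"]))
            rows.append((subject, side, muscle, "length", geo.length_cm,
                         QUANTITY_UNITS["length"]))
    records = pd.DataFrame(
        rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"]
    )
    anth = None
    if config.anthropometrics_csv is not None:
        anth = pd.read_csv(config.anthropometrics_csv, comment="#")
    return CohortTable(records, anth)


def stats_stage(cohort: CohortTable, config: RunConfig, out: Path) -> dict:
    """Run all cohort statistics, write report CSVs, return a summary dict."""
    prov = config.provenance()
    gate_table = (
        pd.read_csv(config.repeatability_csv)
        if config.repeatability_csv is not None
        else None
    )
    gated = apply_repeatability_gate(gate_table)
    gated.to_csv(out / "repeatability_report.csv", index=False)
    retained = retained_muscles(gate_table)

    summary: dict = {"provenance": prov, "retained_muscles": len(retained)}
    denom = config.limb_diff_denominator
    for quantity in ("volume", "length", "pcsa"):
        if (cohort.records["quantity"] == quantity).any():
            res = limb_comparison(cohort, quantity, denominator=denom,
                                  alpha=config.alpha, lilliefors=config.lilliefors)
            if res:
                comparisons_to_frame(res).to_csv(
                    out / f"limb_comparison_{quantity}.csv", index=False
                )
            covs = between_subject_cov(cohort, quantity)
            covs.to_csv(out / f"between_subject_cov_{quantity}.csv", index=False)
            summary[f"cov_{quantity}_min_pct"] = float(covs["cov_pct"].min())
            summary[f"cov_{quantity}_max_pct"] = float(covs["cov_pct"].max())
    has_forces = (cohort.records["quantity"] == "fmax_vls").any() and (
        cohort.records["quantity"] == "fmax_llms"
    ).any()
    if has_forces:
        res = compare_fmax_methods(cohort, denominator=config.fmax_diff_denominator,
                                   alpha=config.alpha, lilliefors=config.lilliefors)
        comparisons_to_frame(res).to_csv(out / "fmax_method_comparison.csv", index=False)
    if cohort.anthropometrics is not None:
        reg_rows = []
        for pred in ("body_mass_kg", "height_cm", "limb_mass_kg", "bmi"):
            if pred in cohort.anthropometrics:
                muscles = [m for m in retained if m in set(cohort.muscles())] or None
                r = regress_vtot(cohort, pred, muscles)
                reg_rows.append(
                    {"predictor": pred, "slope": r.slope, "intercept": r.intercept,
                     "r_squared": r.r_squared, "p_value": r.p_value, "n": r.n}
                )
                summary[f"r2_{pred}"] = r.r_squared
        if reg_rows:
            pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    if config.make_figures:
        from .plots import plot_limb_comparison

        for quantity in ("volume", "length", "pcsa"):
            f = out / f"limb_comparison_{quantity}.csv"
            if f.exists():
                plot_limb_comparison(
                    cohort, quantity, out / f"limb_comparison_{quantity}.png",
                    denominator=denom,
                )
    return summary


def run_all(config: RunConfig) -> dict:
    """Full pipeline; returns the stats summary dict.

    Stage 1 resolves the cohort from (in priority order) label volumes, an
    existing cohort CSV, or the synthetic generator; stage 2 appends PCSA and
    forces; stage 3 writes the statistical report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    if config.volumes_dir is not None:
        cohort = geometry_stage(config)
    elif config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv, config.anthropometrics_csv)
    else:
        synth = dict(config.synth or {})
        synth.setdefault("rng_seed", config.seed)
        cohort = make_cohort(CohortSpec(**synth))
    write_cohort_csv(cohort, out / "cohort_measured.csv", prov)
    if cohort.anthropometrics is not None:
        write_anthropometrics_csv(cohort, out / "anthropometrics.csv", prov)

    ref = reference_tables(config)
    cohort = add_params_to_cohort(cohort, ref)
    write_cohort_csv(cohort, out / "cohort_full.csv", prov)

    summary = stats_stage(cohort, config, out)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
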