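"""Synthetic phantoms and cohorts with analytically known ground truth.

Two generators stand in for the study's MRI data:

* tube-like muscle phantoms (straight, curved or tapered) rasterised on an
  anisotropic voxel grid, with analytic volume and centreline arc length;
* bilateral cohorts of muscles x sides x subjects with controlled
  between-subject coefficient of variation and between-limb percentage
  differences, plus correlated anthropometrics.

Rasterisation rule: a voxel belongs to the mask iff its centre lies inside
the analytic solid, which is placed at a seed-drawn sub-voxel offset so
analytic faces never coincide with voxel-centre planes.  Curved tubes are
torus sectors cut flat at the arc endpoints' axial planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .io import QUANTITY_UNITS, CohortTable, LabelVolume

RadiusProfile = Callable[[np.ndarray], np.ndarray]


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Specification of a tube-like muscle phantom.

    ``axis_length_mm`` is the centreline arc length.  ``radius_mm`` may be a
    constant, a (start, end) pair (linear taper), or a callable of the
    normalised axial position t in [0, 1] returning mm.  ``curvature_per_mm``
    is 1/R of the circular centreline arc (0 = straight).
    """

    shape_kind: str = "straight_tube"  # straight_tube | curved_tube | tapered_tube
    axis_length_mm: float = 60.0
    radius_mm: float | tuple[float, float] | RadiusProfile = 10.0
    curvature_per_mm: float = 0.0
    voxel_spacing_mm: tuple[float, float, float] = (1.1, 1.1, 5.0)
    slice_axis: int = 2
    rng_seed: int = 0

    def radius_profile(self) -> RadiusProfile:
        r = self.radius_mm
        if callable(r):
            return r
        if isinstance(r, (tuple, list)):
            r0, r1 = float(r[0]), float(r[1])
            return lambda t: r0 + (r1 - r0) * t
        return lambda t: np.full_like(np.asarray(t, dtype=float), float(r))

    def validate(self) -> None:
        if self.shape_kind not in ("straight_tube", "curved_tube", "tapered_tube"):
            raise PhantomSpecError(f"unknown shape_kind {self.shape_kind!r}")
        if self.axis_length_mm <= 0:
            raise PhantomSpecError("axis_length_mm must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise PhantomSpecError("voxel spacing must be strictly positive")
        t = np.linspace(0, 1, 101)
        radii = np.asarray(self.radius_profile()(t), dtype=float)
        if np.any(radii <= 0):
            raise PhantomSpecError("all radii must be positive")
        in_plane = [s for i, s in enumerate(self.voxel_spacing_mm) if i != self.slice_axis]
        if radii.min() < max(in_plane) / 2:
            raise PhantomSpecError(
                f"minimum radius {radii.min():.2f} mm is below half the in-plane "
                f"voxel size; shape not resolvable on this grid"
            )
        if self.shape_kind == "curved_tube":
            if self.curvature_per_mm <= 0:
                raise PhantomSpecError("curved_tube needs curvature_per_mm > 0")
            if 1.0 / self.curvature_per_mm <= radii.max():
                raise PhantomSpecError("centreline radius must exceed tube radius")


def _analytic_volume_mm3(spec: PhantomSpec) -> float:
    """Analytic solid volume of the phantom, independent of any voxel grid.

    Straight and tapered tubes are solids of revolution (Pappus: integral of
    pi*r(t)^2 along the axis).  Curved tubes are torus sectors clipped flat
    at the arc endpoints' axial planes; their volume is computed by dense 2D
    quadrature of the exact cross-section areas (relative error ~1e-4, far
    below rasterisation error at any spacing of interest).
    """
    profile = spec.radius_profile()
    if spec.shape_kind in ("straight_tube", "tapered_tube"):
        t = np.linspace(0.0, 1.0, 20001)
        r = np.asarray(profile(t), dtype=float)
        return float(np.trapezoid(np.pi * r**2, t) * spec.axis_length_mm)
    R = 1.0 / spec.curvature_per_mm
    half = spec.axis_length_mm / R / 2
    rmax = float(np.max(profile(np.linspace(0, 1, 101))))
    # circle centre at origin; arc point at angle a: (-R cos a, R sin a);
    # solid: |alpha| <= half, distance to circle <= r(alpha), |z| <= R sin(half)
    zs = np.linspace(-R * np.sin(half), R * np.sin(half), 1501)
    xs = np.linspace(-(R + rmax), -(R - rmax) * np.cos(half) + 1e-9, 1501)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    u = np.hypot(X, Z)
    alpha = np.arctan2(Z, -X)
    r_a = profile(np.clip((alpha + half) / (2 * half), 0, 1))
    h2 = r_a**2 - (u - R) ** 2
    width = np.where((np.abs(alpha) <= half) & (h2 > 0), 2 * np.sqrt(np.maximum(h2, 0)), 0.0)
    area = np.trapezoid(width, xs, axis=0)
    return float(np.trapezoid(area, zs))


def make_phantom(spec: PhantomSpec):
    """Rasterise a phantom; return ``(LabelVolume, ground_truth)``.

    ground_truth keys: ``volume_cm3``, ``centreline_length_cm``,
    ``centreline_points_mm`` (analytic samples), ``rng_seed``.
    """
    spec.validate()
    sx, sy, sz = spec.voxel_spacing_mm
    if spec.slice_axis != 2:
        raise PhantomSpecError("phantoms are generated with slice_axis=2")
    L = spec.axis_length_mm
    profile = spec.radius_profile()
    rmax = float(np.max(profile(np.linspace(0, 1, 101))))
    margin = 2  # voxels of padding around the solid
    # sub-voxel placement offset: grid-aligned analytic faces would put voxel
    # centres exactly on the boundary (a degenerate, biased configuration);
    # real anatomy sits at an arbitrary offset, so draw one from the seed
    rng = np.random.default_rng(spec.rng_seed)
    ux, uy, uz = rng.uniform(0.05, 0.95, size=3)

    if spec.shape_kind in ("straight_tube", "tapered_tube"):
        # axis along z from z0, centred in-plane
        cx = (int(np.ceil(rmax / sx)) + margin + ux) * sx
        cy = (int(np.ceil(rmax / sy)) + margin + uy) * sy
        z0 = (margin + uz) * sz
        nx = int(np.ceil((cx + rmax) / sx)) + margin + 1
        ny = int(np.ceil((cy + rmax) / sy)) + margin + 1
        nz = int(np.ceil((z0 + L) / sz)) + margin + 1
        x = np.arange(nx) * sx
        y = np.arange(ny) * sy
        z = np.arange(nz) * sz
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        t = (Z - z0) / L
        inside_span = (t >= 0) & (t <= 1)
        r_t = profile(np.clip(t, 0, 1))
        inside = inside_span & ((X - cx) ** 2 + (Y - cy) ** 2 <= r_t**2)
        ts = np.linspace(0, 1, 201)
        ctr = np.stack(
            [np.full_like(ts, cx), np.full_like(ts, cy), z0 + ts * L], axis=1
        )
    else:  # curved_tube: circular arc in the x-z plane
        R = 1.0 / spec.curvature_per_mm
        theta_max = L / R
        if theta_max >= np.pi:
            raise PhantomSpecError("arc spans half a turn or more; not supported")
        # The arc is symmetric about the slice axis (tangent +z at mid-arc),
        # as lower-limb muscles run roughly along the scanner's z axis; the
        # per-slice method degrades when the axis turns into the slice plane.
        half = theta_max / 2
        if half > np.pi / 2 - 0.1:
            raise PhantomSpecError("end tangents too close to the slice plane")
        # arc point at angle a in [-half, half]: c + R * (-cos a, sin a)
        cy = (int(np.ceil(rmax / sy)) + margin + uy) * sy
        cx0 = (margin + ux) * sx + R + rmax
        cz0 = (margin + uz) * sz + R * np.sin(half) + rmax
        nx = int(np.ceil((cx0 - R * np.cos(half) + rmax) / sx)) + margin + 1
        ny = int(np.ceil((cy + rmax) / sy)) + margin + 1
        nz = int(np.ceil((cz0 + R * np.sin(half) + rmax) / sz)) + margin + 1
        x = np.arange(nx) * sx
        y = np.arange(ny) * sy
        z = np.arange(nz) * sz
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        vx = X - cx0
        vz = Z - cz0
        u = np.hypot(vx, vz)  # in-plane distance from circle centre
        alpha = np.arctan2(vz, -vx)  # 0 at mid-arc, +/-half at the ends
        dist2 = (u - R) ** 2 + (Y - cy) ** 2
        r_t = profile(np.clip((alpha + half) / theta_max, 0, 1))
        # flat axial end cut at the arc endpoints' planes: keeps every
        # occupied slice transverse to the tube and the centreline's axial
        # span equal to the solid's
        in_span = (Z >= cz0 - R * np.sin(half)) & (Z <= cz0 + R * np.sin(half))
        inside = (alpha >= -half) & (alpha <= half) & (dist2 <= r_t**2) & in_span
        ts = np.linspace(-half, half, 201)
        ctr = np.stack(
            [cx0 - R * np.cos(ts), np.full_like(ts, cy), cz0 + R * np.sin(ts)],
            axis=1,
        )

    arr = inside.astype(np.int16)
    vol = LabelVolume(
        arr,
        spacing=(sx, sy, sz),
        slice_axis=spec.slice_axis,
        label_map={1: ("phantom", "right")},
    )
    ground_truth = {
        "volume_cm3": _analytic_volume_mm3(spec) / 1000.0,
        "centreline_length_cm": L / 10.0,
        "centreline_points_mm": ctr,
        "rng_seed": spec.rng_seed,
    }
    return vol, ground_truth


# ---------------------------------------------------------------------------
# Synthetic bilateral cohorts
# ---------------------------------------------------------------------------


def default_muscle_table() -> pd.DataFrame:
    """Per-muscle defaults: mean volume (cm3) with its SD, mean length (cm)
    for the 23 analysed lower-limb muscles of the study population."""
    with resources.files("musclemetrics.data").joinpath("cohort_defaults.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class CohortSpec:
    """Specification of a synthetic bilateral cohort.

    ``muscle_table`` needs columns muscle, mean_volume_cm3 and either
    cov_volume_pct or sd_volume_cm3, plus mean_length_cm.  Asymmetry is a
    signed percentage difference d drawn per subject-muscle with mean
    ``limb_diff_mean_pct`` and SD ``limb_diff_sd_pct``, applied as
    left = right * (1 - d/100), so d = (right-left)/right*100 exactly.
    ``mass_volume_corr`` is the correlation between body mass and the latent
    subject size factor; ``volume_shared_frac`` is the fraction of each
    muscle's between-subject variance carried by that shared factor (the
    rest is muscle-idiosyncratic), so summed cohort volume correlates with
    body mass at roughly ``mass_volume_corr * sqrt(volume_shared_frac)``.
    """

    n_subjects: int = 11
    muscle_table: pd.DataFrame = field(default_factory=default_muscle_table)
    limb_diff_mean_pct: float = 0.0
    limb_diff_sd_pct: float = 15.0
    length_cov_pct: float = 8.0
    length_diff_sd_pct: float = 3.0
    body_mass_mean_kg: float = 66.9
    body_mass_sd_kg: float = 7.7
    height_mean_cm: float = 159.0
    height_sd_cm: float = 3.0
    mass_volume_corr: float = 0.75
    volume_shared_frac: float = 0.6
    limb_mass_fraction: float = 0.32
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        t = self.muscle_table
        if "cov_volume_pct" not in t.columns:
            if "sd_volume_cm3" not in t.columns:
                raise ValueError("muscle_table needs cov_volume_pct or sd_volume_cm3")
            t = t.assign(cov_volume_pct=100 * t["sd_volume_cm3"] / t["mean_volume_cm3"])
            self.muscle_table = t
        if (t["cov_volume_pct"] < 0).any() or self.length_cov_pct < 0:
            raise ValueError("CoVs must be non-negative")
        if (t["mean_volume_cm3"] <= 0).any() or (t["mean_length_cm"] <= 0).any():
            raise ValueError("means must be strictly positive")


def _truncated_scale(rng, base: np.ndarray, frac_sd: np.ndarray) -> np.ndarray:
    """Multiplicative factors 1 + frac_sd * z, resampled until positive."""
    out = 1.0 + frac_sd * base
    bad = out <= 0
    while bad.any():
        out[bad] = 1.0 + frac_sd[bad] * rng.standard_normal(int(bad.sum()))
        bad = out <= 0
    return out


def make_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a bilateral cohort; deterministic given ``spec.rng_seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    t = spec.muscle_table
    muscles = list(t["muscle"])
    n, m = spec.n_subjects, len(muscles)
    rho = spec.mass_volume_corr

    z_mass = rng.standard_normal(n)
    body_mass = spec.body_mass_mean_kg + spec.body_mass_sd_kg * z_mass
    body_mass = np.clip(body_mass, 30.0, None)
    # latent subject size factor, correlated with body mass
    z_subject = rho * z_mass + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    height = spec.height_mean_cm + spec.height_sd_cm * rng.standard_normal(n)
    bmi = body_mass / (height / 100.0) ** 2
    limb_mass = spec.limb_mass_fraction * body_mass * (
        1 + 0.03 * rng.standard_normal(n)
    )

    cov = t["cov_volume_pct"].to_numpy() / 100.0  # (m,)
    mean_v = t["mean_volume_cm3"].to_numpy()
    mean_l = t["mean_length_cm"].to_numpy()
    a = np.sqrt(spec.volume_shared_frac)
    eps = rng.standard_normal((n, m))
    mixed = a * z_subject[:, None] + np.sqrt(1 - a**2) * eps
    right_v = mean_v[None, :] * _truncated_scale(rng, mixed, np.broadcast_to(cov, (n, m)).copy())
    d = spec.limb_diff_mean_pct + spec.limb_diff_sd_pct * rng.standard_normal((n, m))
    left_v = right_v * (1 - d / 100.0)
    bad = left_v <= 0
    while bad.any():
        d[bad] = spec.limb_diff_mean_pct + spec.limb_diff_sd_pct * rng.standard_normal(
            int(bad.sum())
        )
        left_v = right_v * (1 - d / 100.0)
        bad = left_v <= 0

    lcov = np.full((n, m), spec.length_cov_pct / 100.0)
    right_l = mean_l[None, :] * _truncated_scale(rng, rng.standard_normal((n, m)), lcov)
    dl = spec.length_diff_sd_pct * rng.standard_normal((n, m))
    left_l = right_l * np.clip(1 - dl / 100.0, 1e-6, None)

    subjects = [f"S{i + 1:02d}" for i in range(n)]
    rows = []
    for i, subj in enumerate(subjects):
        for j, muscle in enumerate(muscles):
            for side, v, l in (
                ("right", right_v[i, j], right_l[i, j]),
                ("left", left_v[i, j], left_l[i, j]),
            ):
                rows.append((subj, side, muscle, "volume", v, QUANTITY_UNITS["volume"]))
                rows.append((subj, side, muscle, "length", l, QUANTITY_UNITS["length"]))
    records = pd.DataFrame(
        rows, columns=["subject_id", "side", "muscle", "quantity", "value", "unit"]
    )
    anth = pd.DataFrame(
        {
            "subject_id": subjects,
            "body_mass_kg": body_mass,
            "height_cm": height,
            "bmi": bmi,
            "limb_mass_kg": limb_mass,
            "dominant_side": "right",
            "rng_seed": spec.rng_seed,
        }
    )
    return CohortTable(records, anth)
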