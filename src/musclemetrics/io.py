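"""Reading and writing of label volumes and cohort tables.

Label volumes are 3D integer grids with anisotropic voxel spacing in mm.
Physical coordinates follow the voxel-centre convention: the centre of voxel
``(i, j, k)`` sits at ``(i*sx, j*sy, k*sz)`` mm, with the origin at the first
voxel centre.  Cohort data live in a long-format table with one record per
(subject, side, muscle, quantity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

SIDES = ("right", "left")

#: canonical quantity names and the units they are reported in
QUANTITY_UNITS: dict[str, str] = {
    "volume": "cm3",
    "length": "cm",
    "pcsa": "cm2",
    "fmax_vls": "N",
    "fmax_llms": "N",
}

COHORT_COLUMNS = ["subject_id", "side", "muscle", "quantity", "value", "unit"]


class LabelVolumeError(ValueError):
    """Raised for malformed or inconsistent label volumes."""


@dataclass
class LabelVolume:
    """A 3D label map with voxel spacing in mm.

    Parameters
    ----------
    voxel_array
        3D integer array; 0 is background, positive values are labels.
    spacing
        Voxel spacing (mm) per array axis.
    slice_axis
        Array axis treated as the inferior-superior (acquisition slice) axis.
    label_map
        Maps each label value to a ``(muscle, side)`` pair.
    """

    voxel_array: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    label_map: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxel_array = np.asarray(self.voxel_array)
        if self.voxel_array.ndim != 3:
            raise LabelVolumeError("voxel_array must be 3D")
        if not np.issubdtype(self.voxel_array.dtype, np.integer):
            raise LabelVolumeError("voxel_array must be integer-typed")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise LabelVolumeError("spacing must be three strictly positive values (mm)")
        if self.slice_axis not in (0, 1, 2):
            raise LabelVolumeError("slice_axis must be 0, 1 or 2")
        present = set(np.unique(self.voxel_array)) - {0}
        if self.label_map:
            unknown = present - set(self.label_map)
            if unknown:
                raise LabelVolumeError(
                    "labels present in voxels but absent from label map: "
                    f"{sorted(int(u) for u in unknown)}"
                )
            for lab, (muscle, _side) in self.label_map.items():
                if lab not in present:
                    warnings.warn(
                        f"label {lab} ({muscle}) has no foreground voxels; muscle flagged absent",
                        stacklevel=2,
                    )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def labels_present(self) -> list[int]:
        return sorted(set(np.unique(self.voxel_array)) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.voxel_array == label


def _spacing_scale_to_mm(img: nib.Nifti1Image) -> float:
    units, _ = img.header.get_xyzt_units()
    return {"unknown": 1.0, "mm": 1.0, "meter": 1000.0, "micron": 1e-3}.get(units, 1.0)


def read_label_volume(
    path: str | Path,
    label_map: Mapping[int, tuple[str, str]] | str | Path | None = None,
) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) label volume.

    Spacing is normalised to mm regardless of on-disk units; labels are
    preserved exactly.  ``label_map`` may be a mapping or the path of a CSV
    with columns ``label,muscle,side``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        if any(z == 0 for z in zooms):
            raise LabelVolumeError(f"{path}: missing or zero spacing metadata")
        scale = _spacing_scale_to_mm(img)
        spacing = tuple(float(z) * scale for z in zooms)
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise LabelVolumeError(f"{path}: non-integer voxel values in a label volume")
        data = rounded.astype(np.int32)
    lm = _load_label_map(label_map)
    return LabelVolume(data, spacing, slice_axis=2, label_map=lm)


def _load_label_map(label_map) -> dict[int, tuple[str, str]]:
    if label_map is None:
        return {}
    if isinstance(label_map, (str, Path)):
        df = pd.read_csv(label_map)
        required = {"label", "muscle", "side"}
        if not required <= set(df.columns):
            raise ValueError(f"label map CSV needs columns {sorted(required)}")
        return {int(r.label): (str(r.muscle), str(r.side)) for r in df.itertuples()}
    return {int(k): (str(v[0]), str(v[1])) for k, v in dict(label_map).items()}


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI or MetaImage, spacing in mm."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        img = nib.Nifti1Image(volume.voxel_array.astype(np.int16), affine)
        img.header.set_zooms(volume.spacing)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(volume.voxel_array.transpose(2, 1, 0).astype(np.int16))
        img.SetSpacing(volume.spacing)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def write_label_map(label_map: Mapping[int, tuple[str, str]], path: str | Path) -> None:
    rows = [
        {"label": lab, "muscle": m, "side": s} for lab, (m, s) in sorted(label_map.items())
    ]
    pd.DataFrame(rows, columns=["label", "muscle", "side"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Long-format cohort data plus per-subject anthropometrics.

    ``records`` has columns (subject_id, side, muscle, quantity, value, unit);
    at most one record per (subject, side, muscle, quantity), values strictly
    positive.  Missing muscles are simply absent records, never zeros.
    ``anthropometrics`` (optional) is indexed by subject_id with columns such
    as body_mass_kg, height_cm, bmi, limb_mass_kg, dominant_side.
    """

    records: pd.DataFrame
    anthropometrics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=COHORT_COLUMNS).copy()
        df["value"] = df["value"].astype(float)
        validate_records(df)
        self.records = df.reset_index(drop=True)
        if self.anthropometrics is not None:
            a = pd.DataFrame(self.anthropometrics)
            if a.index.name != "subject_id":
                if "subject_id" in a.columns:
                    a = a.set_index("subject_id")
                else:
                    raise ValueError("anthropometrics need a subject_id column or index")
            self.anthropometrics = a

    def subjects(self) -> list:
        return sorted(self.records["subject_id"].unique())

    def muscles(self) -> list[str]:
        return sorted(self.records["muscle"].unique())

    def pivot_sides(self, quantity: str) -> pd.DataFrame:
        """Wide view for one quantity: rows (subject, muscle), columns right/left."""
        sub = self.records[self.records["quantity"] == quantity]
        return sub.pivot_table(
            index=["subject_id", "muscle"], columns="side", values="value", aggfunc="first"
        )

    def with_records(self, new: pd.DataFrame) -> "CohortTable":
        new = pd.DataFrame(new, columns=COHORT_COLUMNS)
        if new.empty:
            return CohortTable(self.records, self.anthropometrics)
        merged = pd.concat([self.records, new])
        return CohortTable(merged, self.anthropometrics)


def validate_records(df: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad_side = set(df["side"].unique()) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown side values: {sorted(bad_side)}")
    if (df["value"] <= 0).any():
        rows = df[df["value"] <= 0].head()
        raise ValueError(f"non-positive values in cohort table:\n{rows}")
    key = ["subject_id", "side", "muscle", "quantity"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate records:\n{df[dup].head()}")


def read_cohort_csv(
    path: str | Path, anthropometrics_path: str | Path | None = None
) -> CohortTable:
    """Read a long-format cohort CSV (comment lines starting with # ignored)."""
    df = pd.read_csv(path, comment="#")
    anth = None
    if anthropometrics_path is not None:
        anth = pd.read_csv(anthropometrics_path, comment="#")
    return CohortTable(df, anth)


def write_cohort_csv(
    table: CohortTable, path: str | Path, provenance: str | None = None
) -> None:
    """Write the long-format records; full float precision for round-trips."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.records.to_csv(fh, index=False, float_format="%.17g")


def write_anthropometrics_csv(
    table: CohortTable, path: str | Path, provenance: str | None = None
) -> None:
    if table.anthropometrics is None:
        raise ValueError("cohort table has no anthropometrics")
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.anthropometrics.to_csv(fh, float_format="%.17g")


def wide_to_long(
    wide: pd.DataFrame, quantity: str, unit: str | None = None
) -> pd.DataFrame:
    """Melt a supplementary-style wide table into long cohort records.

    The wide layout has a ``muscle`` column and one column per subject-side
    named ``<subject>_right`` / ``<subject>_left`` (muscles as rows, subjects
    as columns).  Empty cells become absent records, not zeros.
    """
    if "muscle" not in wide.columns:
        raise ValueError("wide table needs a 'muscle' column")
    unit = unit or QUANTITY_UNITS.get(quantity, "")
    long = wide.melt(id_vars="muscle", var_name="subject_side", value_name="value")
    long = long.dropna(subset=["value"])
    split = long["subject_side"].str.rsplit("_", n=1, expand=True)
    if split.shape[1] != 2 or not set(split[1].unique()) <= set(SIDES):
        raise ValueError("wide columns must be named <subject>_right / <subject>_left")
    long["subject_id"] = split[0]
    long["side"] = split[1]
    long["quantity"] = quantity
    long["unit"] = unit
    return long[COHORT_COLUMNS].reset_index(drop=True)
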