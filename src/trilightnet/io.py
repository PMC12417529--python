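"""Volume and clinical-table I/O.

Volumes are NIfTI-1 files handled through nibabel and kept in memory as
:class:`VolumeGrid` objects with a fixed ``[depth, height, width]`` axis
order and the voxel-to-world affine passed through untouched (inputs
are assumed co-registered and skull-stripped, so voxels that are
exactly zero are background).

The clinical table is a CSV with one row per subject and the seven
features used for conversion prediction: age, gender, education, ApoE4
allele count, CSF phospho-tau 181, CSF total tau, and an FDG/AV45 PET
composite.  Continuous features are z-scored with statistics computed
on training subjects only; the two coded features (gender, ApoE4) pass
through as numeric codes.  Missing values are errors, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "VolumeGrid",
    "ClinicalRecord",
    "CohortTable",
    "CLINICAL_FEATURES",
    "CONTINUOUS_FEATURES",
    "read_volume",
    "write_volume",
    "resize_volume",
    "intensity_normalize",
    "load_clinical_table",
    "save_clinical_table",
]

#: canonical feature order of the 7-dimensional clinical vector
CLINICAL_FEATURES = (
    "age",
    "gender",
    "education",
    "apoe4",
    "ptau181",
    "ttau",
    "fdg_av45_composite",
)

#: features standardized with training-set statistics
CONTINUOUS_FEATURES = ("age", "education", "ptau181", "ttau", "fdg_av45_composite")

REQUIRED_COLUMNS = ("subject_id",) + CLINICAL_FEATURES + ("label",)


@dataclass
class VolumeGrid:
    """One 3-D image: voxels [depth, height, width] plus its affine."""

    voxels: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected 3D volume for subject {self.subject_id!r}, "
                f"got {self.voxels.ndim}D"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("volume shape must be positive in each axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"non-finite voxels in volume for subject {self.subject_id!r}")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class ClinicalRecord:
    """One subject's clinical feature vector and conversion label."""

    subject_id: str
    age: float
    gender: int
    education: float
    apoe4: float
    ptau181: float
    ttau: float
    fdg_av45_composite: float
    label: int

    def feature_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CLINICAL_FEATURES], dtype=np.float64)


@dataclass
class CohortTable:
    """Ordered clinical records plus the standardization statistics
    (computed from training subjects only) that produced them."""

    records: list[ClinicalRecord]
    feature_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort table")

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def feature_matrix(self) -> np.ndarray:
        return np.stack([r.feature_vector() for r in self.records])

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


# ---------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------

def read_volume(path) -> VolumeGrid:
    """Load a NIfTI-1 file as a :class:`VolumeGrid`.

    Raises on missing files, non-3D images and NaN voxels; the error
    message names the offending subject (the file stem).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    subject = path.name.removesuffix(".gz").removesuffix(".nii")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume for subject {subject!r}, got {data.ndim}D")
    if np.isnan(data).any():
        raise ValueError(f"NaN voxels in volume for subject {subject!r}")
    return VolumeGrid(voxels=data, affine=np.asarray(img.affine), subject_id=subject)


def write_volume(v: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1, preserving the affine."""
    if not np.all(np.isfinite(v.voxels)):
        raise ValueError("refusing to write non-finite voxels")
    img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), v.affine)
    nib.save(img, str(path))


def resize_volume(v: VolumeGrid, target: tuple[int, int, int]) -> VolumeGrid:
    """Trilinear resample onto ``target`` = (depth, height, width).

    Uses the half-pixel-center convention: target voxel center i maps to
    source coordinate (i + 0.5) * S/T - 0.5.  The affine is rescaled so
    voxel centers keep their world positions.
    """
    target = tuple(int(t) for t in target)
    if min(target) < 1:
        raise ValueError("resize target must be positive in every axis")
    src = v.voxels.shape
    if target == src:
        return VolumeGrid(v.voxels.copy(), v.affine.copy(), v.subject_id)
    scales = [s / t for s, t in zip(src, target)]
    axes_coords = [
        (np.arange(t) + 0.5) * sc - 0.5 for t, sc in zip(target, scales)
    ]
    grid = np.meshgrid(*axes_coords, indexing="ij")
    out = map_coordinates(
        np.asarray(v.voxels, dtype=np.float64),
        np.stack([g.ravel() for g in grid]),
        order=1,
        mode="nearest",
    ).reshape(target)
    new_affine = v.affine.copy()
    offset = np.array([0.5 * sc - 0.5 for sc in scales])
    new_affine[:3, :3] = v.affine[:3, :3] * np.array(scales)[None, :]
    new_affine[:3, 3] = v.affine[:3, 3] + v.affine[:3, :3] @ offset
    return VolumeGrid(out.astype(v.voxels.dtype, copy=False), new_affine, v.subject_id)


def intensity_normalize(v: VolumeGrid) -> VolumeGrid:
    """Z-score the foreground (voxels with |value| > 0); background
    stays exactly zero.  Constant foreground is an error."""
    vox = np.asarray(v.voxels, dtype=np.float64)
    mask = np.abs(vox) > 0
    if not mask.any():
        raise ValueError(f"all-zero volume for subject {v.subject_id!r}")
    fg = vox[mask]
    sd = fg.std()
    if sd == 0:
        raise ValueError(
            f"zero-variance foreground for subject {v.subject_id!r}: cannot normalize"
        )
    out = np.zeros_like(vox)
    out[mask] = (fg - fg.mean()) / sd
    return VolumeGrid(out.astype(np.float32), v.affine.copy(), v.subject_id)


# ---------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------

def load_clinical_table(path, training_ids=None) -> CohortTable:
    """Parse the clinical CSV and standardize continuous features using
    statistics from ``training_ids`` only (``None`` uses every row,
    appropriate only when no held-out evaluation follows)."""
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {missing_cols}")
    df = df[list(REQUIRED_COLUMNS)].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in clinical table columns: {bad}")
    df["subject_id"] = df["subject_id"].astype(str)
    if not df["gender"].isin([0, 1]).all():
        raise ValueError("unknown gender code (expected 0 or 1)")
    if not df["apoe4"].isin([0, 1, 2]).all():
        raise ValueError("apoe4 must be an allele count in {0, 1, 2}")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("label must be 0 (sMCI) or 1 (pMCI)")

    if training_ids is None:
        training_ids = set(df["subject_id"])
    else:
        training_ids = {str(i) for i in training_ids}
    unknown = training_ids - set(df["subject_id"])
    if unknown:
        raise ValueError(f"training ids absent from table: {sorted(unknown)[:5]}")
    train_rows = df[df["subject_id"].isin(training_ids)]
    if len(train_rows) < 2:
        raise ValueError("zero variance: need at least 2 training rows to standardize")

    stats: dict[str, tuple[float, float]] = {}
    for feat in CONTINUOUS_FEATURES:
        mu = float(train_rows[feat].mean())
        sd = float(train_rows[feat].std(ddof=0))
        if sd == 0:
            raise ValueError(f"zero variance in training rows for feature {feat!r}")
        stats[feat] = (mu, sd)
        df[feat] = (df[feat] - mu) / sd

    records = [
        ClinicalRecord(
            subject_id=row.subject_id,
            age=float(row.age),
            gender=int(row.gender),
            education=float(row.education),
            apoe4=float(row.apoe4),
            ptau181=float(row.ptau181),
            ttau=float(row.ttau),
            fdg_av45_composite=float(row.fdg_av45_composite),
            label=int(row.label),
        )
        for row in df.itertuples(index=False)
    ]
    return CohortTable(records=records, feature_stats=stats)


def save_clinical_table(records: list[ClinicalRecord], path) -> None:
    """Write raw (unstandardized) clinical records as CSV."""
    rows = [
        {
            "subject_id": r.subject_id,
            **{f: getattr(r, f) for f in CLINICAL_FEATURES},
            "label": r.label,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
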