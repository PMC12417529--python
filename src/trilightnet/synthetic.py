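"""Synthetic cohort generator.

Emulates the structure of a conversion-prediction cohort — paired,
co-registered MRI-like and PET-like volumes plus a seven-feature
clinical table — with controllable class effects, so every pipeline
stage can be exercised without access-restricted imaging data.

Each subject is a bright ellipsoidal "brain" (intensity 1, background
exactly 0, matching the skull-stripped convention) carrying smoothed
Gaussian noise; converters (label 1) lose ``delta`` intensity inside a
fixed modality-specific ellipsoid (an atrophy-like focus in the MRI, a
hypometabolism-like focus in the PET).  Clinical features are drawn
from class-conditional normals (age, education, both tau markers, the
FDG/AV45 composite; base means loosely patterned on published MCI
cohort demographics, e.g. age ~ N(73, 7^2)) and class-specific
Bernoullis/categoricals (gender, ApoE4 allele count).  Class-1 mean
shifts are expressed in units of the base standard deviation.

The default shape 24 x 32 x 24 keeps the 3:4:3 aspect of the real
96 x 128 x 96 grid, so the ``test`` encoder preset produces the same
36-token feature layout.  The generator does not attempt realistic
neuroanatomy; what it guarantees is a controlled, reproducible
class-conditional signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import (
    CLINICAL_FEATURES,
    ClinicalRecord,
    VolumeGrid,
    intensity_normalize,
    save_clinical_table,
    write_volume,
)
from .train import ArrayDataset

__all__ = [
    "Ellipsoid",
    "EffectSpec",
    "SyntheticCohort",
    "gen_subject",
    "gen_cohort",
    "cohort_to_dataset",
    "write_cohort",
]

DEFAULT_SHAPE = (24, 32, 24)

# base (sMCI) clinical distributions: mean, sd for continuous features
_BASE_CONTINUOUS = {
    "age": (73.0, 7.0),
    "education": (16.0, 2.7),
    "ptau181": (28.0, 12.0),
    "ttau": (280.0, 110.0),
    "fdg_av45_composite": (1.15, 0.12),
}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in unit-cube fractions of the volume."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self):
        for c, r in zip(self.center, self.radii):
            if r <= 0:
                raise ValueError("ellipsoid radii must be positive")
            if c - r < 0 or c + r > 1:
                raise ValueError("ellipsoid region extends outside the unit cube")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(
            *[(np.arange(n) + 0.5) / n for n in shape], indexing="ij"
        )
        dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii))
        return dist <= 1.0


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth class effects baked into a synthetic cohort."""

    mri_region: Ellipsoid = Ellipsoid((0.38, 0.52, 0.42), (0.16, 0.14, 0.16))
    mri_delta: float = 0.5
    pet_region: Ellipsoid = Ellipsoid((0.58, 0.32, 0.55), (0.16, 0.16, 0.16))
    pet_delta: float = 0.5
    clinical_shifts: dict = field(
        default_factory=lambda: {
            "age": 0.3,
            "education": -0.3,
            "ptau181": 1.5,
            "ttau": 1.5,
            "fdg_av45_composite": -1.5,
        }
    )
    noise_sigma: float = 0.2
    smoothing: float = 1.0
    brain_radii: tuple[float, float, float] = (0.46, 0.47, 0.46)
    gender_p: tuple[float, float] = (0.5, 0.55)  # P(gender=1) per class
    apoe4_p: tuple[tuple, tuple] = ((0.6, 0.3, 0.1), (0.3, 0.45, 0.25))

    def __post_init__(self):
        if self.mri_delta < 0 or self.pet_delta < 0:
            raise ValueError("class-effect deltas must be >= 0")

    @classmethod
    def null(cls) -> "EffectSpec":
        """All class effects switched off (the sanity-null condition)."""
        return cls(
            mri_delta=0.0,
            pet_delta=0.0,
            clinical_shifts={f: 0.0 for f in _BASE_CONTINUOUS},
            gender_p=(0.5, 0.5),
            apoe4_p=((0.6, 0.3, 0.1), (0.6, 0.3, 0.1)),
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    subjects: list[tuple[VolumeGrid, VolumeGrid, ClinicalRecord]]
    truth: EffectSpec
    seed: int

    def labels(self) -> dict[str, int]:
        return {rec.subject_id: rec.label for _, _, rec in self.subjects}


def _gen_volume(label, region, delta, spec, shape, rng):
    brain = Ellipsoid((0.5, 0.5, 0.5), spec.brain_radii).mask(shape)
    vox = np.zeros(shape, dtype=np.float32)
    noise = gaussian_filter(rng.standard_normal(shape), spec.smoothing)
    vox[brain] = 1.0 + spec.noise_sigma * noise[brain]
    if label == 1 and delta > 0:
        effect = region.mask(shape) & brain
        vox[effect] -= delta
    affine = np.eye(4)
    return vox, affine


def _gen_clinical(label, spec, rng, subject_id) -> ClinicalRecord:
    values = {}
    for feat, (mu, sd) in _BASE_CONTINUOUS.items():
        shift = spec.clinical_shifts.get(feat, 0.0) if label == 1 else 0.0
        values[feat] = float(rng.normal(mu + shift * sd, sd))
    values["ptau181"] = max(values["ptau181"], 1.0)
    values["ttau"] = max(values["ttau"], 10.0)
    gender = int(rng.random() < spec.gender_p[label])
    apoe4 = int(rng.choice(3, p=np.asarray(spec.apoe4_p[label]) / np.sum(spec.apoe4_p[label])))
    return ClinicalRecord(
        subject_id=subject_id,
        age=values["age"],
        gender=gender,
        education=values["education"],
        apoe4=float(apoe4),
        ptau181=values["ptau181"],
        ttau=values["ttau"],
        fdg_av45_composite=values["fdg_av45_composite"],
        label=int(label),
    )


def gen_subject(
    label: int,
    spec: EffectSpec = EffectSpec(),
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    subject_id: str | None = None,
) -> tuple[VolumeGrid, VolumeGrid, ClinicalRecord]:
    """One paired subject; bit-identical for identical (label, seed)."""
    if min(shape) < 1:
        raise ValueError("volume shape must be positive")
    if label not in (0, 1):
        raise ValueError("label must be 0 (stable) or 1 (progressive)")
    sid = subject_id if subject_id is not None else f"synth-{seed:08d}"
    rng = np.random.default_rng(seed)
    mri_vox, affine = _gen_volume(label, spec.mri_region, spec.mri_delta, spec, shape, rng)
    pet_vox, _ = _gen_volume(label, spec.pet_region, spec.pet_delta, spec, shape, rng)
    record = _gen_clinical(label, spec, rng, sid)
    return (
        VolumeGrid(mri_vox, affine, sid),
        VolumeGrid(pet_vox, affine.copy(), sid),
        record,
    )


def gen_cohort(
    n_pos: int,
    n_neg: int,
    spec: EffectSpec = EffectSpec(),
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int = 0,
) -> SyntheticCohort:
    """Exactly n_pos converters and n_neg stable subjects with unique
    ids; per-subject seeds derive from the master seed."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject per class")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_pos + n_neg)
    subjects = []
    labels = [1] * n_pos + [0] * n_neg
    for i, (label, s) in enumerate(zip(labels, child_seeds)):
        subjects.append(
            gen_subject(label, spec, shape, int(s), subject_id=f"sub-{i:04d}")
        )
    return SyntheticCohort(subjects=subjects, truth=spec, seed=seed)


def cohort_to_dataset(cohort: SyntheticCohort, train_ids) -> ArrayDataset:
    """Normalize volumes and standardize clinical features (statistics
    from ``train_ids`` only) into an in-memory training dataset."""
    train_ids = {str(i) for i in train_ids}
    ids, mris, pets, feats, labels = [], [], [], [], []
    for mri, pet, rec in cohort.subjects:
        ids.append(rec.subject_id)
        mris.append(intensity_normalize(mri).voxels)
        pets.append(intensity_normalize(pet).voxels)
        feats.append(rec.feature_vector())
        labels.append(rec.label)
    feats = np.stack(feats)
    train_mask = np.array([i in train_ids for i in ids])
    if train_mask.sum() < 2:
        raise ValueError("need at least 2 training subjects to standardize")
    cont_idx = [CLINICAL_FEATURES.index(f) for f in _BASE_CONTINUOUS]
    mu = feats[train_mask][:, cont_idx].mean(axis=0)
    sd = feats[train_mask][:, cont_idx].std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance in a continuous clinical feature")
    feats[:, cont_idx] = (feats[:, cont_idx] - mu) / sd
    return ArrayDataset(
        mri=np.stack(mris)[:, None].astype(np.float32),
        pet=np.stack(pets)[:, None].astype(np.float32),
        clinical=feats.astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        ids=ids,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Serialize as NIfTI pairs + clinical CSV + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for mri, pet, rec in cohort.subjects:
        write_volume(mri, out / f"{rec.subject_id}_mri.nii.gz")
        write_volume(pet, out / f"{rec.subject_id}_pet.nii.gz")
        records.append(rec)
    save_clinical_table(records, out / "clinical.csv")
    (out / "truth.json").write_text(
        json.dumps({"seed": cohort.seed, "effects": cohort.truth.to_dict()}, indent=2)
    )
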