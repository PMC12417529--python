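"""Attribute one prediction to voxels and clinical features.

Trains briefly on synthetic data, then runs midpoint-rule integrated
gradients (64 steps, zero baseline, logit target) for one converter.
Prints the completeness check — attributions should sum to the change
in the logit — and the share of MRI attribution mass falling inside
the planted effect region, plus the per-feature clinical attributions.
"""

import numpy as np

from trilightnet import (
    CLINICAL_FEATURES,
    EffectSpec,
    ModelConfig,
    TrainConfig,
    gen_cohort,
)
from trilightnet.interpret import IgConfig, integrated_gradients
from trilightnet.synthetic import cohort_to_dataset
from trilightnet.train import train_one_fold

spec = EffectSpec()
cohort = gen_cohort(16, 16, spec, seed=21)
ids = [rec.subject_id for _, _, rec in cohort.subjects]
data = cohort_to_dataset(cohort, ids)

model, _ = train_one_fold(
    data, np.arange(24), np.arange(24, 32), ModelConfig(),
    TrainConfig(epochs=6, batch_size=8, lr=1e-3, seed=21),
)

i = 0  # first subject is a converter
attr = integrated_gradients(
    model, data.mri[i, 0], data.pet[i, 0], data.clinical[i], IgConfig(steps=64)
)
print(f"logit change from baseline: {attr.output_delta:+.4f}")
print(f"completeness gap at m=64:   {attr.completeness_gap:.5f} "
      f"({100 * attr.completeness_gap / abs(attr.output_delta):.2f}% of the change)")

region = spec.mri_region.mask(data.mri.shape[2:])
inside = np.abs(attr.mri_attr[region]).sum()
total = np.abs(attr.mri_attr).sum()
print(f"MRI attribution mass inside planted region: {100 * inside / total:.1f}% "
      f"(region covers {100 * region.mean():.1f}% of the volume)")
for name, value in zip(CLINICAL_FEATURES, attr.clinical_attr):
    print(f"  clinical {name:<22}{value:+.4f}")
print("A small completeness gap certifies the attribution; concentrated mass "
      "in the planted region shows the model looks where the signal is.")
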