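"""Generate a small synthetic cohort and inspect the planted effects.

Builds 10 converters (pMCI-like) and 20 stable subjects with the
default strong class effects, then measures the mean intensity inside
the MRI effect region per class: the difference should sit near the
planted delta (0.5), and the shifted CSF tau features should differ by
about 1.5 standard deviations.
"""

import numpy as np

from trilightnet import EffectSpec, gen_cohort

spec = EffectSpec()
cohort = gen_cohort(n_pos=10, n_neg=20, spec=spec, seed=7)

region = spec.mri_region.mask((24, 32, 24))
means = {0: [], 1: []}
ptau = {0: [], 1: []}
for mri, pet, rec in cohort.subjects:
    means[rec.label].append(mri.voxels[region].mean())
    ptau[rec.label].append(rec.ptau181)

drop = np.mean(means[0]) - np.mean(means[1])
print(f"subjects: {len(cohort.subjects)} (10 pMCI / 20 sMCI)")
print(f"MRI effect-region intensity  stable={np.mean(means[0]):.3f}  "
      f"converter={np.mean(means[1]):.3f}  drop={drop:.3f} (planted delta {spec.mri_delta})")
print(f"P-tau 181  stable={np.mean(ptau[0]):.1f}  converter={np.mean(ptau[1]):.1f} pg/mL")
print("The intensity drop recovers the planted atrophy-like effect; the "
      "tau shift mirrors the configured 1.5-sd clinical separation.")
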