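# trilightnet

A lightweight triple-modal fusion network for predicting conversion
from mild cognitive impairment (MCI) to Alzheimer's disease.  The
model, TriLightNet, integrates three inputs per subject — a structural
MRI volume, an FDG-PET volume, and seven clinical features (age,
gender, education, ApoE4 allele count, CSF P-tau 181, CSF total tau,
FDG/AV45 composite) — to classify progressive (pMCI) versus stable
(sMCI) subjects.  The package is aimed at researchers who want a
fully inspectable, dependency-light reference implementation of the
architecture, its training/evaluation protocol, and its
integrated-gradients interpretability, runnable end to end on a CPU
via a built-in synthetic-cohort generator (real cohort data such as
ADNI are access-restricted and never required).

## Model

- **Imaging encoders**: one 3-D ResNet (basic residual blocks) per
  modality; the `full` preset maps 96 × 128 × 96 volumes to a
  [256, 3, 4, 3] feature map, the `test` preset is a ÷4-width,
  ×8-downsampling replica for CPU-scale runs.
- **Tabular encoder**: a single Kolmogorov–Arnold (KAN) layer with
  cubic B-spline edge functions `w_b·SiLU(x) + w_s·Σ c_r B_r(x)`,
  followed by M = 2 PoolFormer blocks
  (`H' = H + AvgPool(LN(H))`, `H = H' + MLP(LN(H'))`).
- **HBAM** injects the embedded clinical vector into CBAM-style
  channel attention, `M_hc = σ(MLP(GAP F) + MLP(GMP F) + Embed F_cli)`,
  followed by 7×7×7 spatial attention; with a zero embedding it is
  exactly CBAM.
- **MMCA** fuses the two refined token streams with grouped, cascaded,
  bidirectional cross-attention
  (`v̂ᵢˣ = softmax(qᵢʸᵀkᵢˣ/√d_k + bᵢ)vᵢˣᵀ`, N = 4 groups, learnable
  L × L positional bias), concatenating to a [B, L, 2C] fused
  representation scored by a small MLP head.
- **Focal loss** `−α_t(1−p_t)^γ log p_t` (α = 0.75, γ = 2) handles the
  149:363 class imbalance; **Adam** with a cosine schedule
  (T_max = 50), early stopping (patience 50) and stratified five-fold
  cross-validation complete the protocol.
- **Integrated gradients** attributes predictions to every voxel and
  clinical feature via the midpoint path sum, with the completeness
  axiom checked numerically and NIfTI overlay export.

Everything runs on a small reverse-mode autodiff core over NumPy
(`trilightnet.autodiff`) — no deep-learning framework is needed; 3-D
convolutions are im2col + BLAS products and every gradient is
finite-difference-tested.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains the `test` preset on a 60-subject synthetic cohort (strong
planted effects, a third held out) and prints:

```
training loss by epoch: [0.0751, 0.0002, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0034]
held-out (20 subjects): balanced accuracy=1.000 AUROC=1.000 F1=1.000
```

The falling focal loss shows optimization working; perfect held-out
separation means the network recovered the planted class signal — a
0.5-intensity decrement in fixed MRI/PET regions plus 1.5-sd shifts of
the CSF tau markers and PET composite.  Other examples generate
cohorts (`01`), attribute a prediction with integrated gradients
(`03` — prints a completeness gap of 0.52% of the logit change at
m = 64 and finds 63.5% of the MRI attribution mass inside the planted
region, which covers 1.5% of the volume), and reproduce the published
30/73 / 119/290 cohort split arithmetic with five-fold sizes
{82, 82, 82, 82, 81} (`04`).

A thin CLI covers the same ground from a shell:

```bash
trilightnet synth --n-pos 30 --n-neg 73 --seed 1 --out cohort/
trilightnet cv --data cohort/ --seed 1 --out cv.json
trilightnet train --data cohort/ --seed 1 --out model.ckpt.npz
trilightnet explain --checkpoint model.ckpt.npz --data cohort/ --subject sub-0000 --out ig/
```

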