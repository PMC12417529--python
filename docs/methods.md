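# Methods

## Problem and model

The package predicts conversion from mild cognitive impairment (MCI)
to Alzheimer's disease — progressive (pMCI) versus stable (sMCI) —
from three co-registered inputs per subject: a structural MRI volume,
an FDG-PET volume (both resampled to a fixed grid, 96 × 128 × 96 at
full scale), and seven clinical features (age, gender, education,
ApoE4 allele count, CSF P-tau 181, CSF total tau, and an FDG/AV45 PET
composite).  The network, TriLightNet, has four parts:

1. **Imaging encoders.**  One 3-D ResNet per modality (basic residual
   blocks: two 3×3×3 convolutions plus identity/projection shortcut;
   7×7×7 stride-2 stem + stride-2 max pool).  Weights are not shared
   between MRI and PET: the modalities have different intensity
   statistics.  `full` preset: widths (32, 64, 128, 256), 2 blocks per
   stage, stage strides (1, 2, 2, 2) → total downsampling ×32, feature
   map [256, 3, 4, 3].  `test` preset: widths (8, 16, 32, 64), 1 block
   per stage, strides (1, 2, 1, 1) → ×8, feature map [64, 3, 4, 3].
   Both yield L = 36 tokens, so every downstream shape is shared.

2. **Tabular encoder.**  A single Kolmogorov–Arnold (KAN) layer whose
   edge functions are `w_b·SiLU(x) + w_s·Σ c_r B_r(x)` on a uniform
   cubic B-spline grid (G = 5 intervals over [−2, 2] on standardized
   inputs; G + k = 8 basis functions; inputs beyond the range follow
   the polynomial extension of the boundary pieces).  The 64-d output
   is reshaped to 8 tokens × 8 channels and refined by M = 2
   PoolFormer blocks — LayerNorm, a kernel-3 stride-1 token average
   pool that averages only existing neighbours, and a 4× GELU MLP,
   each behind a residual.  The pooling residual is applied literally
   as `H + AvgPool(LN(H))` (no identity subtraction).  A config switch
   (`use_kan=False`) swaps the KAN layer for linear-plus-SiLU, which
   is the tabular-encoder ablation; nothing else changes.

3. **HBAM** (hybrid block attention).  Channel gates are
   `σ(MLP(GAP(F)) + MLP(GMP(F)) + W·F_cli + b)`; spatial gates come
   from a 7×7×7 convolution over the channel-mean/max maps.  Both
   gates lie in (0, 1), so HBAM only shrinks magnitudes and preserves
   signs, and with a zero clinical embedding it reduces exactly to
   CBAM (a property the tests exploit).  Bottleneck ratio r = 8 at
   full width; the final MLP layer carries no bias so an all-zero MLP
   yields exactly 0.5 gates.  Each imaging branch has its own HBAM;
   information flows clinical → image only.

4. **MMCA** (multimodal cascaded attention).  Tokens [B, L, C] from
   each refined branch are split into N = 4 channel groups of width
   d_k = C/N.  Within group i, modality X attends with the *other*
   modality's queries: `v̂ᵢˣ = softmax(qᵢʸᵀkᵢˣ/√d_k + bᵢ)·vᵢˣᵀ` and
   symmetrically for Y; bᵢ is a learnable L × L positional bias,
   zero-initialized and shared by the two directions of a group.  The
   cascade adds each modality's attended output of group i−1 to its
   own channel slice of group i (same-modality cascading; feeding
   across modalities was the open alternative).  Group outputs are
   concatenated, projected per modality, and the fused representation
   is concat(Z_x, Z_y) ∈ [B, L, 2C].  Q/K/V maps are bias-free
   channel maps; projections carry biases.

   The classification head mean-pools over tokens, then
   LayerNorm → Linear(2C → 64) → GELU → Linear(64 → 1), a single
   pMCI logit through a sigmoid.

## Loss

Focal loss handles the 149:363 class imbalance.  Default form:
`−α_t (1−p_t)^γ log p_t` with `p_t = p` for converters and `1−p`
otherwise, `α_t = α` / `1−α`, defaults α = 0.75 (up-weighting the
minority converter class), γ = 2 — standard choices; no values are
prescribed by the protocol itself.  A `literal_form` flag provides the
variant in which a single `(1−p)^γ` factor multiplies the whole
cross-entropy; it is kept for fidelity to the printed formula but not
used by default, because it also down-weights confident positives.
Probabilities are clamped to [1e-7, 1−1e-7].  At γ = 0, α = 1 the
literal form is exactly cross-entropy; the default form matches
cross-entropy wherever α_t = 1.

## Training protocol

Adam, batch size 8, learning rate 1e-4, cosine schedule
`lr(e) = lr₀(1 + cos(π(e mod T_max)/T_max))/2` with T_max = 50, up to
200 epochs, early stopping on validation focal loss with patience 50;
stratified five-fold cross-validation carved from the training split
only, with each fold's best model also scored on the single held-out
test split.  The 4:1 split rounds the per-class test count half-up
(`round(0.2·n_class)`), which reproduces the published 30/73 test and
119/290 train composition exactly; the published counts are consistent
with per-class rounding, so stratification is adopted.  One master
seed derives the split, fold, initialization and batch-order seeds by
fixed offsets, making every run bit-reproducible.

Metrics: accuracy, sensitivity, precision, F1, specificity, balanced
accuracy = (sensitivity + specificity)/2, and AUROC from the midrank
Mann–Whitney statistic (ties get half credit).  Undefined ratios are
reported as NaN with a warning rather than silently coerced.
Parameter counts come from traversal of the named arrays; FLOPs are
2 × multiply–accumulates of every convolution, linear map and
attention product, counted by the numerical core during one forward
pass at the configured input shape.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over NumPy arrays (`trilightnet.autodiff`)
with exactly the operations the network needs.  3-D convolution runs
as im2col + BLAS matrix products; its input gradient uses the
transposed-convolution offset loop (27 or 343 strided slice updates),
which is memory-light and exact for any stride/padding combination.
Softmax subtracts the row maximum, so attention rows remain normalized
even for ±1e4 logits.  Batch norm uses batch statistics (momentum 0.1
running updates) in training and running statistics in evaluation;
LayerNorm ε = 1e-5.  All gradients are validated against central
finite differences in the test suite.  Default parameter dtype is
float32; oracle-equivalence tests promote modules to float64 where
1e-12 agreement is asserted.

## Integrated gradients

`IG_i = (x_i − x'_i) · (1/m) Σ_s ∂F/∂x_i` evaluated at the midpoint
path points `x' + (s−½)/m (x − x')`, jointly over the MRI volume, PET
volume and clinical vector.  Baseline: zero volumes and zero clinical
vector (the standard choice for z-scored inputs, where zero is the
cohort mean); target: the pre-sigmoid logit, so completeness is exact
in the linear limit; default m = 64.  The midpoint rule is used
instead of the left-endpoint sum because it converges one order
faster for smooth integrands.  The completeness gap
`|Σ IG − (F(x) − F(x'))|` is computed and reported with every
attribution; voxel maps can be exported as NIfTI overlays on the
input grid with optional sign-preserving normalization to [−1, 1].

## Synthetic cohort

The generator produces what the pipeline needs to be testable without
restricted clinical data: a bright ellipsoidal "brain" (intensity 1,
background exactly 0, matching the skull-stripped convention) with
smoothed Gaussian noise (σ = 0.2 after smoothing width 1 voxel), and
for converters an intensity decrement δ = 0.5 inside a fixed
modality-specific ellipsoid — an atrophy-like MRI focus and a
hypometabolism-like PET focus.  Clinical features are class-
conditional: continuous draws (age ≈ N(73, 7²), education ≈
N(16, 2.7²), P-tau ≈ N(28, 12²), T-tau ≈ N(280, 110²), composite ≈
N(1.15, 0.12²); base values loosely patterned on published MCI cohort
demographics) with converter shifts of +0.3, −0.3, +1.5, +1.5, −1.5
standard deviations respectively, gender Bernoulli(0.5/0.55) and
ApoE4 categorical ((.6,.3,.1) vs (.3,.45,.25)).  `EffectSpec.null()`
switches every effect off for null-calibration checks.  The default
24 × 32 × 24 shape keeps the 3:4:3 aspect of the full grid so the
`test` encoder preset sees the same 36-token layout.

What the generator does *not* emulate: real neuroanatomy, registration
artifacts, scanner/site effects, missing modalities, or correlated
clinical noise.  Passing the synthetic checks therefore demonstrates
that the architecture, optimization and attribution machinery work
and can recover a planted multimodal signal at these sizes — not that
the model attains any particular accuracy on clinical cohorts.

## Scaled-down study sizes

The bundled checks and the reproduction script run on one CPU, and
their problem sizes are chosen accordingly as the package's own
defaults: the planted-signal recovery check trains the `test` preset
for 30 epochs on 120 subjects (53:127 cohort, one third held out →
60 evaluation subjects) with learning rate 1e-3 — the larger rate
suits the short schedule; the reference-protocol 1e-4/200-epoch setting
remains the default `TrainConfig`.  The same run with all effects
zeroed calibrates the null.  The fusion-ablation comparison (full
model vs HBAM+MMCA replaced by concatenation) uses 3 seeds at 80
training / 40 held-out subjects, 12 epochs.  The integrated-gradients
completeness study uses a model trained 6 epochs on 32 subjects and
step counts m ∈ {16, 64, 256}.

## Known limitations

- The backbone depth/width of the original study is unpublished; the
  presets here are reasonable reconstructions, so parameter/FLOP
  totals are not comparable surfaces.
- Training at full 96 × 128 × 96 scale is supported by the code paths
  but is far slower than the framework-based original; the package is
  a reference implementation, not a performance port.
- α and γ of the focal loss and all tabular-encoder dimensions are
  package choices (documented above), as none are prescribed.
- Attention biases make the token count L part of the architecture;
  volumes of a different shape require building a new model.
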