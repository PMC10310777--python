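# Methods

## Problem and model

Contrast-enhanced and non-contrast chest CT differ by a localized intensity
boost (several hundred HU) in vascular and cardiac structures.  Mixing the
two acquisition types in one dataset shifts intensity statistics and can
confound radiomics and deep-learning models.  `cyclect` implements an
unpaired style-transfer approach: a 3D patch-based cycle-consistent GAN
that learns the contrast → non-contrast mapping (and its inverse) from two
cohorts that share no paired scans, plus the evaluation machinery needed to
decide whether such a synthesis is trustworthy.

Two generators G_AB (contrast → non-contrast) and G_BA (non-contrast →
contrast) are trained against two patch-GAN discriminators D_A, D_B.  For
patches a ~ domain A (contrast) and b ~ domain B (non-contrast), the
generator objective is

    L = L_adv(A,B) + L_cyc + λ · L_idt,         λ = 10

with

* **adversarial** (least-squares form): `mean((D_B(G_AB(a)) − 1)²)` and the
  symmetric term for G_BA.  The discriminators minimize
  `½[mean((D(real) − 1)²) + mean(D(fake)²)]`.  The adversarial objective is
  sometimes written in log (minimax) form; because the discriminator loss is
  specified as a mean squared error we adopt the least-squares GAN form for
  both players — it is the consistent choice and is known to train more
  stably.  Only this form is implemented.
* **cycle consistency**: `(L1 + L_SSIM) / 2` between a patch and its
  round-trip reconstruction, where `L_SSIM = 1 − SSIM`.
* **identity**: mean absolute change when a generator receives a patch
  already in its output domain, `mean|G_AB(b) − b|` and `mean|G_BA(a) − a|`.
  Note that the weight λ multiplies the identity term only; the cycle term
  enters with weight 1.

### SSIM

SSIM is computed over 3D neighborhoods with a Gaussian window (σ = 1.5,
7³ support — smaller than the common 11³ so that windows fit comfortably
inside small training patches), constants C1 = (0.01·L)², C2 = (0.03·L)²
with dynamic range L = 2 for patches in [−1, 1].  Local maps are evaluated
on the valid interior (no boundary padding) and averaged.  The window
parameters are a package choice; absolute loss magnitudes therefore depend
on them and are not comparable across SSIM implementations.  The analytic
gradient of the windowed SSIM is implemented and verified against finite
differences.

### Architecture

Generator: one reflection-padded encoding convolution
(ReflectionPad–Conv3D–InstanceNorm–ReLU), two stride-2 down blocks, a stack
of residual units (two 3³ convolutions each, instance-normalized), two
stride-2 transposed-convolution up blocks, and a final reflection-padded
convolution with Tanh.  Discriminator: three stride-2 blocks
(Conv3D k=4 – InstanceNorm – LeakyReLU 0.2), one 3³ convolution to a single
channel, sigmoid; on a cube of side s it emits an (s/8)³ grid of local
realism scores.

Presets:

| preset     | base filters | residual units | encode/final kernel |
|------------|-------------|----------------|---------------------|
| full-scale | 64          | 9              | 7³                  |
| tiny       | 8           | 2              | 3³                  |

The tiny preset exists so the full training loop runs on one CPU core in
minutes; shrinking the encode/decode kernels from 7³ to 3³ is part of that
preset (kernel sizes are spec fields) because the two full-resolution 7³
convolutions dominate the small model's runtime while contributing nothing
at phantom complexity.  Weight init is N(0, 0.02); instance normalization
uses ε = 1e-5 and no affine terms; transposed convolutions use k=3, stride
2, padding 1, output padding 1 so a down/up round trip restores the side
exactly.

All networks and their gradients run on a small numpy/BLAS engine
(`cyclect.nn`): convolutions are expressed as single GEMMs plus strided
slab gathers/scatters, with the formulation (buffers proportional to
C_in·K vs C_out·K) chosen per layer.  Every layer is verified against
finite differences, and the transposed convolution against a brute-force
evaluation of its defining sum.

### Training loop

Per iteration (batch size 1): sample one random cubic patch per domain
(corners uniform over valid positions; optional rejection of all-air
patches is available but off by default), take one joint Adam step on both
generators (all six forward paths: translation, reconstruction, identity,
for both directions), then one Adam step per discriminator using a
50-image history pool of previously generated patches (standard practice;
size 0 disables it).  Adam uses lr 2e-4, β1 = 0.5, β2 = 0.999, constant —
no decay schedule.  All randomness (init, patch positions, pool swaps)
flows from one seeded stream, so runs are bit-reproducible on fixed
hardware.  The full-scale preset (64³ patches, 450k iterations) is a
configuration, not a test.

### Inference

Whole volumes are translated window by window on a stride-16 grid (patch
64 at full scale, 32 at desk scale), with the last window per axis clamped
to the boundary so every voxel is covered without padding the volume (the
generator never sees synthetic padding values).  Overlapping predictions
are blended with a separable tent weight t(i)·t(j)·t(k), where t rises
linearly from a floor of ε = 0.05 at the patch border to 1 at the center.
Any weighting that is maximal at the center satisfies the design intent;
the tent is the simplest such function, and the floor keeps voxels covered
by a single window well defined.  Accumulation uses double-precision
buffers, so the result is independent of window visiting order and is
testable against a brute-force oracle at 1e-6.

## Synthetic data

Real cohort data (hospital chest CTs with manual contrast labels) are not
redistributable, so the package generates procedural thorax phantoms: an
ellipsoidal body (40 HU) in air (−1000 HU), two ellipsoidal lungs
(−800 HU), and 2–4-voxel-radius polyline tubes (60 HU) standing in for
vessels; the contrast domain adds +300 HU on the tube voxels — the typical
magnitude of arterial enhancement and comfortably inside the [−1000, 1000]
truncation window.  Per-subject geometric jitter (±8 % axis scales and
offsets) and independent Gaussian acquisition noise (20 HU default; 10 HU
in the recovery study so the domain gap is 30 σ) provide between-subject
variability.  Noise is added last and clipped with the volume to
[−1000, 1000], matching the preprocessing clamp.

What the phantoms emulate: two unpaired cohorts that differ *only* by
localized vascular hyperintensity, with hidden paired ground truth and
region masks for evaluation.  What they do not emulate: realistic anatomy
and texture, reconstruction kernels, slice-thickness effects, or
contrast-timing variability.  Passing tests therefore demonstrate that the
training, inference and evaluation machinery behaves correctly on data
with the assumed statistical structure — not that the model reaches
clinical image quality on real CT.

## Desk-scale study conditions

The reference experiments (`cyclect.experiments`) run on 48³ phantom grids
(1×1×2 mm), 4 + 4 unpaired volumes, the tiny presets, 32³ patches, 500
iterations, three seeds.  These sizes were chosen once so that one
training run takes a few CPU-minutes; at these conditions the
contrast-removal generator reliably reduces the vessel-region error
against the hidden paired truth by well over half while leaving
non-contrast inputs nearly unchanged (the identity property).

## Evaluation arms

* **Reader study**: confusion tables are reconstructed from published
  operating points (sensitivity/specificity with the positive class fixed
  as "acquired"; that assignment is the only one consistent with all the
  published panel numbers).  A binary rater is a single ROC operating point,
  so its AUC is (sens + spec)/2.  Fleiss' kappa follows the standard
  item-by-category count formulation; when every rating falls in one
  category chance agreement is 1 and kappa is reported as undefined rather
  than guessed.  An optional large-sample z statistic (standard Fleiss
  variance) is provided but cannot be checked against published studies
  that do not release the raw rating matrix.
* **Pooled deep features**: slices are body-masked (threshold −500 HU,
  5×5 opening, slice-wise hole filling), byte-normalized by
  y = floor(255(x+1000)/2000) clipped to [0, 255] (clipping applied after
  the floor), replicated to RGB, and pushed through a frozen convolutional
  backbone; per-channel global maxima form the feature vector.  "Global
  max over the final convolutional grid" is the reading adopted for the
  pooling step.  The default backbone is a small random-weight stack —
  random projections suffice to expose intensity-level differences, which
  is all the harness itself needs; a pretrained 512-channel backbone plugs
  into the same contract where its weights are available.  The desk-scale
  reference experiments pool 32 random channels — wide enough for the
  vessel-contrast gap to register reliably in random projections — and
  train the head to convergence (250 epochs, 8 resampled-validation
  repeats) so the trivially separable comparisons actually reach their
  ceiling.  One caveat is intrinsic to random features at this scale: the
  tiny generator leaves texture fingerprints that random projections
  detect with ease, so the synthetic-vs-acquired comparison saturates at
  AUC 1.0, and for some random-feature draws the acquired-contrast
  comparison can land marginally below its own ceiling.  The qualitative
  ordering (acquired ≥ synthetic ≥ shuffled ≈ 0.5) is therefore asserted
  at the documented study conditions rather than claimed for every seed.  The classifier
  head follows the published design exactly — sigmoid hidden layers
  (256…16), He-uniform init, L1 penalty on weights and biases (coefficient
  1e-5 by default, configurable), sigmoid output, Adam +
  BCE — even though sigmoid hiddens with He init is an unusual pairing.
  The published split (160 train, 48-patient validation resampled per
  repeat) is internally inconsistent with a 200-patient 80:20 split; the
  implementation resamples a balanced validation subset of configurable
  size from the pool each repeat and trains on the remainder.
* **Radiomics drift**: correlated-feature removal is the greedy
  mean-absolute-correlation heuristic at threshold 0.9 (the behavior of
  the common R tooling), Kendall selection keeps |tau-b| ≥ 0.2 (absolute
  value — sign handling is unstated and either sign is informative), and
  drift is 100·|post − pre|/|pre| per subject and feature with zero
  denominators excluded and tallied rather than substituted.  ROC AUC is
  the Mann–Whitney rank statistic (ties ½); two ROC curves on the same
  subjects are compared by a paired stratified bootstrap with a normal
  approximation on the resampled difference distribution.  Full texture
  feature panels are external inputs; phantom runs use first-order
  intensity statistics per region mask, which exercise the machinery
  end-to-end.  Feature standardization before modeling is configurable and
  off by default (the reference recipe does not specify it).

## Numerical choices

float32 network arithmetic with float64 loss/metric reductions;
double-precision sliding-window accumulators; SSIM maps in float64;
correlation/selection tie-breaks are lexicographic on feature names so
results are order-independent; degenerate inputs (empty masks, constant
labels, single-category ratings, zero-variance features) raise or warn
explicitly instead of producing silent numbers.

## Known limitations

The desk-scale experiments demonstrate mechanism, not clinical image
quality; published loss magnitudes of comparable models are not directly
reproducible because the SSIM
window and several schedule details are package choices; the phantom
generator's simplicity means discriminators face a far easier task than on
real CT; and the numpy engine is single-threaded — it is sized for the
tiny preset, while the full-scale preset exists as configuration for
completeness.
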