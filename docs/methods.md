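# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open.

## Network architectures

Both feature extractors are built from *bottleneck-residual blocks*: a
batchnorm → 1×1 conv → ReLU → batchnorm → 3×3 conv → ReLU → batchnorm →
1×1 conv → ReLU stack, with an identity shortcut when input and output
shapes match and a 1×1 projection otherwise. Batchnorm sits *before* each
convolution; this is unconventional but is the stated layer order of the
designs being reproduced, and it trains stably in practice.

* **three_block** — stem conv(32, 3×3, s2) → ReLU → maxpool(3×3, s1), then
  three groups; each group applies two bottleneck blocks *in parallel* to
  the same input, merges them by element-wise addition (concatenation
  would double widths and break the 2,048-wide GAP contract), and
  downsamples with conv(3×3, s2) → ReLU → maxpool(3×3, s1). Group widths:
  (64,64,64), (96,96,320), (320,320,640).
* **four_block** — the same stem followed by four sequential bottleneck
  blocks, widths (64,64,64), (64,64,64), (160,160,160), (352,352,480);
  blocks 2–4 downsample via a stride-2 middle conv with a projection
  shortcut.
* **head** — conv(1024, 3×3, s2) → ReLU → conv(2048) → ReLU → global
  average pooling → dense(2) → softmax.

Two global constraints calibrate these designs: the GAP feature width is
exactly 2,048, and the learnable-parameter totals are 15.9M (three-block)
and 25.1M (four-block). The interior channel widths are otherwise free;
the schedules above were solved numerically once against the totals and
frozen. For the three-block net the totals force one further choice: a
3×3 conv from 1,024 to 2,048 channels alone holds 18.9M weights, more
than the whole 15.9M budget, so its 2,048-wide head conv is pointwise
(1×1); the four-block budget accommodates the 3×3 version, which it keeps.
Counts include conv kernels, biases, batchnorm scale/shift and dense
weights; they are independent of the RNG seed and of input size.

Convolutions and pooling use ceil-mode "same" padding (output size
⌈H/s⌉), so a 227×227 input reaches the head at 4×4 and the networks
accept any input of 64×64 or larger — parameter counts and the GAP width
are unaffected, which is how desk-scale runs keep forward passes cheap.

"Hidden-layer" counts of the original designs are narrated ambiguously
(whether activations and pooling count is unstated), so layer totals are
not enforced; the parameter totals and GAP width are.

## The numpy layer engine

No deep-learning framework is part of the dependency set; the layers
(conv via im2col/col2im with BLAS matmuls, batchnorm with full train-mode
backward, maxpool, GAP, dense, softmax, residual and parallel-add
containers) are implemented directly in numpy with explicit backward
passes. The engine is validated by central-difference gradient checks
(relative error ~1e-6 in float64) and batch-invariance tests. Training is
mini-batch SGD with classical momentum (v ← μv − lr·g). Activations are
float32; single-threaded runs are bit-deterministic given the seed.

After training, batchnorm running statistics are *recalibrated*: one
forward pass over (a sample of up to 256 of) the training images in
training mode with zeroed momentum replaces the exponential running
averages with population moments under the final weights. Short training
runs otherwise leave the averages lagging the weights, which depresses
inference-mode accuracy without affecting the training-mode loss.

Grad-CAM backpropagates the selected class probability to the last
convolutional layer, weights each channel by the spatial mean of its
gradient, applies ReLU to the weighted sum, bilinearly upsamples to the
input size and min–max normalizes to [0,1]; a constant map is returned as
zeros.

## Synthetic data

The generator emulates the statistical structure each stage assumes, not
mammographic physics:

* **Images** (default 227×227, minimum 64×64): background is a
  low-frequency Gaussian random field plus pixel noise scaled to roughly
  [0.2, 0.6]; malignant images add 1–3 anisotropic Gaussian blobs whose
  contrast is 0.15 + 0.45·effect, with ground-truth masks at the
  half-maximum support; benign images optionally carry one faint
  (0.05-contrast) smooth blob. `effect` ∈ [0,1] controls class
  separability; at 0.9 a brightest-percentile threshold classifier
  separates the classes at ≥90% training accuracy, so a working pipeline
  should too. Gray values are replicated to three channels to match the
  networks' input depth.
* **Correlated feature pairs**: both views load a shared standard-normal
  latent on one unit direction with independent unit-variance Gaussian
  noise; the signal scale s = √(r/(1−r)) makes the population first
  canonical correlation equal the requested r. Calibration is checked
  against a classical CCA oracle (mean over 20 seeds within 0.05 at
  n=500).
* **Selection benchmarks**: informative columns are Gaussians whose class
  means differ by `shift` (default 1.0) standard deviations at scattered,
  recorded indices; the rest are label-independent standard Gaussians.

Passing tests on these generators shows the pipeline recovers planted
structure under its own assumptions; it says nothing about texture,
acquisition artifacts, label noise or the class overlap of real
mammograms.

## Kernel-CCA fusion

`gaussian_kernel` uses K[i,j] = exp(−‖fᵢ−fⱼ‖²/2σ²) with the median
pairwise distance as the default bandwidth (parameter-free and
scale-adaptive; each view gets its own σ unless one is supplied). Kernels
are double-centered (K′ = HKH). `solve_kcca` reduces the symmetric-block
generalized eigenproblem to a half-size eigenproblem and returns the
leading pair (ξ, η, ρ) under the normalization ξ'K_uK_uξ = η'K_vK_vη = 1,
with the sign fixed so ξ's largest-magnitude entry is positive.

Numerical choices: the Gram blocks K² are rank-deficient by construction,
so a ridge `reg` (default 1e-3) is mandatory — `reg=0` on singular
systems raises with advice rather than returning noise. Kernels are
scaled by 1/N inside the solver so the squared spectrum is O(1) and `reg`
has a sample-size-independent meaning (ρ itself is invariant to the
common rescaling). With the default ridge the solver recovers a planted
r = 0.8 within 0.15 at n = 300 while independent views stay at their
permutation-null level; a linear-kernel hook makes the solver coincide
with classical linear CCA for dual-route testing.

The kernel-space canonical projections live in N-dimensional coefficient
space and cannot span p₁+p₂ output columns, so the *fused matrix* is
defined as the entropy-weighted horizontal concatenation — each column
scaled by its Shannon entropy (256 equal-width bins by default, the 8-bit
intensity convention) normalized by the maximum column entropy — with ρ
retained as a diagnostic and ξ, η exported for inspection. This is the
only reading consistent with a fused width of p₁+p₂ (two 2,048 views →
4,096), and it treats the entropy step as an uncertainty *weighting*:
near-constant, low-information columns shrink toward zero rather than
being dropped.

## Q-GNDO feature selection

The continuous core maintains n ≥ 4 candidates in a box. Per candidate
per iteration a fair coin (no switching rule is prescribed) picks:

* *local exploitation*: trial = ∂ + ς·CT with ∂ = (V_j + V_best + K)/3,
  ς = √[((V_j−∂)² + (V_best−∂)² + (K−∂)²)/3] element-wise, and the signed
  penalty CT = −ln(γ₁)cos(2πγ₂ [+π]). The square root is included because
  the quantity plays the role of a standard deviation in a mean + spread
  sampling rule;
* *global exploration*: trial = V_j + ρ|γ₃|v₁ + (1−ρ)|γ₄|v₂ with v₁, v₂
  fitness-screened differences involving three distinct random others.

A quantum jump follows each GNDO move: Ω = θ·pbest_j + (1−θ)·gbest with
θ ~ U(0,1), trial = Ω ∓ β·|Ḡ − V_j|·ln(1/u), where Ḡ is the mean of
personal bests, the sign is a fair coin, and β contracts linearly from
1.0 to 0.5 over the run (the standard quantum-behaved-swarm schedule; no
β is prescribed). Both proposals are clamped to the box and accepted only
on strict improvement, so the best cost is monotone nonincreasing. All
logs are natural. The ratio |f(best)/f(candidate)| is exported as a
per-iteration diagnostic only; it plays no role in the update.

For feature selection, positions in [0,1]^D binarize at 0.5; the wrapper
cost is 0.99·(1 − CV accuracy) + 0.01·(selected/D), with an empty mask
assigned the worst cost 1.0 to keep the search total. Fitness values are
cached per mask. On benchmarks with 10 informative among 100 columns
(n=300, population 20, 30 iterations) the selector recovers ≥70% of the
planted columns on a 5-seed average.

## Classifiers and metrics

The five presets are hidden-layer *widths* — narrow/medium/wide = one
layer of 10/25/100 ReLU units, bilayered/trilayered = two/three layers of
10 — the reading consistent with the preset names of the point-and-click
toolbox they mirror (the alternative "10 hidden layers" reading
contradicts the names). Training is full-batch L-BFGS behind a per-fold
z-scoring step, so cross-validation never leaks test-fold statistics.
Evaluation pools out-of-fold predictions of a stratified k-fold (default
10) into one confusion matrix.

Sensitivity and precision are macro-averages over the two classes (the
tables being mirrored report single values that differ slightly from
accuracy, which macro-averaging produces and a positive-class-only
convention does not); F1 is the harmonic mean of the macro pair; FNR is
100 − sensitivity by construction; G-measure = √(precision·sensitivity);
MCC and Cohen's kappa use their standard binary formulas ×100; AUC is the
rank statistic on pooled class-1 scores, on the [0,1] scale.

## Paired t-test

Differences are absolute values; σ uses the N−1 denominator;
t = √N·μ/σ with dof N−1 against the two-sided t critical interval
(computed from the distribution, not a table). Two conventions matter for
reproducing printed arithmetic: the √N form is the standard one-sample
statistic on differences (a printed "N·μ/σ" form reproduces the published
value only under √N), and `round_intermediates=3` *truncates* μ and σ
toward zero before forming t, because the printed σ = 0.531 is the
truncation of 0.5315 (rounding would give 0.532) and only the truncated
value reproduces t = 2.919. Exact mode (`round_intermediates=None`)
matches `scipy.stats.ttest_1samp` on the absolute differences to 1e-9.
All-zero differences yield t = 0 with a degenerate flag.

## Training and hyperparameter search

The stratified split is 50:50 by default (per-class train size within one
of half). Augmentation — horizontal flip, vertical flip, +90° and 180°
rotations, a minimal "traditional" set — runs after the split and only on
the training partition, avoiding leakage; which side of the split
augmentation belongs to was an open choice, resolved toward no leakage.
Bayesian optimization is a Gaussian process (Matérn 5/2) with expected
improvement over a seeded 256-point candidate pool, on the box
log₁₀ lr ∈ [−5, −2], momentum ∈ [0.5, 0.99] (the box itself is a design
choice), scored by validation accuracy after a short proxy training.

## Pipeline conventions and desk-scale sizes

The orchestrator derives per-stage seeds from the global seed by hashing
`"{seed}:{stage}"`, so stages are independently reproducible; stages
resume from existing artifacts and re-execute when an input is newer than
their outputs. Networks train on the training partition only; fusion is
unsupervised and uses all rows; selection and classifier CV run on the
test partition by default (`classify.partition: all` evaluates
everything), matching the convention of cross-validating "the testing
results".

Default desk-scale problem sizes: 50 images per class at 96×96 (the
architectures are spatially agnostic, so this changes neither parameter
counts nor the 2,048-wide GAP), 2 training epochs, mini-batch 16,
selection with population 6 over 5 iterations on 4,096 fused columns, and
5-fold CV with two presets. This full chain runs in a few minutes on one
CPU and is byte-deterministic under a fixed seed. Parameter counts and
feature widths are measured at the full 227×227 input in the acceptance
script.

## Known limitations

* The synthetic phantoms are far easier than clinical data; reported
  desk-scale accuracies characterize the pipeline's mechanics, not
  clinical performance.
* The networks train from scratch for a handful of epochs at desk scale;
  the 50-epoch defaults are provided but are CPU-expensive at 227×227.
* Only the leading canonical pair is computed; multi-view (>2) CCA and
  non-Gaussian kernels are out of scope.
* The selected-subset size depends on data and seed; no particular width
  is enforced.
* Batchnorm recalibration assumes the training sample fits one forward
  pass (up to 256 images); extremely small RAM budgets would need
  chunked moment accumulation.
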