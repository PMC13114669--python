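# Methods

## Problem and model

Breast-ultrasound tumor segmentation is a binary dense-prediction
problem on grayscale images dominated by multiplicative speckle, low
lesion/background contrast, and ill-defined margins. The package
implements a triple-branch encoder–decoder:

**Encoder (CNN-anchored hierarchical parallel design).** A residual CNN
backbone produces features at four levels (stem downsamples ×2, stages
1–3 each ×2, so levels sit at 1/2 … 1/16 of the input; channel widths
default to 64/128/256/512 with ResNet-34 stage depths 3/4/6/3). At each
level the CNN feature map is processed *in parallel* by

* a **visual state-space (VSS) block** — a selective state-space model
  (S6). The continuous system h′ = A h + B x, y = C h is discretized by
  a zero-order hold over a per-token step Δ:
  Ā = exp(ΔA), B̄ = (ΔA)⁻¹(exp(ΔA) − I)ΔB (diagonal A; the two-term
  series ΔB(1 + ΔA/2) is used when |ΔA| < 10⁻⁶, which matches the exact
  expression to ~10⁻¹³ at the switch point and has the correct Δ→0
  limit). Δ, B, C are input-dependent linear projections of the token
  (dt_rank = ⌈inner/16⌉, "auto"); A is a learned per-channel diagonal
  initialized to −(1..N), N = d_state = 16 by default. Tokens are
  scanned in four orders (row-major forward/backward, column-major
  forward/backward) and the scan outputs averaged; the block wraps the
  scan in channel expansion (×2), a 3×3 depthwise convolution, SiLU
  gating, and adds a pre-norm feed-forward sublayer (MLP ratio 4)
  mirroring the transformer block;
* a **transformer block** — pre-norm multi-head self-attention over
  flattened pixels (heads 2/4/8/16 per level, MLP ratio 4.0, dropout
  0.1) with learned *factorized* row+column positional embeddings per
  level (summed over the grid; bilinearly resampled if the block is run
  at a different grid). Factorized embeddings carry the same positional
  information as per-token tables at a fraction of the parameters, which
  keeps the branch parameter ordering (CNN-only < +transformer <
  +Mamba < full) independent of image resolution.

**Adaptive feature fusion (AFFM).** Per level and per sample, branch
maps are concatenated → 1×1 convolution → global average pooling →
two-layer MLP (reduction r = 4) → 3 logits → softmax weights wᵢ ≥ 0,
Σwᵢ = 1; the fused map Σ wᵢ Fᵢ feeds the next CNN stage and the decoder.
Ablation alternatives: concatenation+1×1 conv, squeeze-excitation
gating, and an unweighted average.

**Decoder.** U-Net++-style dense nested decoder: nodes X(i,j) for
i + j ≤ 3 receive all same-row predecessors plus the upsampled
(bilinear) node below; row widths equal the encoder widths; a 1×1 head
on X(0,3) yields one logit map, upsampled to the input size. The
"plain" ablation keeps only the X(i,1) chain (a standard U-Net
decoder). The head bias is initialized to −2 so the initial prediction
matches the background-dominated class prior; this removes several
wasted epochs of bias correction on small runs.

**Loss.** L_total = λ₁·L_BCE_weighted + λ₂·L_Dice + λ₃·L_boundary with
λ₁ = λ₂ = λ₃ = 1. The boundary band is morphological dilation minus
erosion of the ground-truth mask with a square 7×7 element
(zero-padded borders). L_BCE_weighted weights band pixels 3.0 vs 1.0
and normalizes by the total weight (comparable scale across lesion
sizes); L_boundary is the unweighted BCE restricted to the band (0 for
an empty band); L_Dice is soft Dice with smoothing 1.0. Probabilities
are clamped at 10⁻⁷ before logs; the training path evaluates BCE on
logits via the softplus identity. The "no-DBR" ablation sets
λ₃ = 0 and equal pixel weights (plain BCE + Dice).

## Training protocol

AdamW, lr 10⁻⁴, weight decay 10⁻⁴, batch 16, ≤100 epochs, cosine
annealing with warm restarts (T₀ = 20 epochs, T_mult = 2, η_min = 0,
stepped per epoch), early stopping patience 30 on validation loss,
lowest-validation-loss checkpoint selected. Augmentation: horizontal
flip (p = 0.5), rotation ±15°, translation ≤5%, scale 0.9–1.1 (no
shear), bilinear for images / nearest + re-binarize for masks. In
K-fold cross-validation the held-out fold doubles as the validation
set (no inner split), and each fold run is seeded with
`base_seed + fold`.

## Synthetic phantoms

The generator emulates the first-order appearance of breast ultrasound:
a smooth tissue background with a mild depth gradient; one or more
hypoechoic star-convex lesions whose radius r(θ) = r₀(1 + a·s(θ)) is
perturbed by a unit-RMS low-order random Fourier series (orders 2–5,
amplitude a = `boundary_irregularity`); an elliptical base shape
(axis ratio 0.65–1, random orientation) with r₀ calibrated from the
polygon area so the realized mask-area fraction tracks the requested
range; interior intensity multiplied by `lesion_contrast` (default
0.45); an optional soft posterior shadow column (probability 0.3);
multiplicative gamma speckle (shape = `speckle_scale` = 6, unit mean);
min–max normalization. Identical (spec, seed, index) triplets are
byte-identical.

What it does **not** model: beamforming/PSF anisotropy, attenuation,
Cooper's-ligament structure, acquisition heterogeneity, annotation
noise, or class imbalance across devices. Passing the end-to-end
benchmark on phantoms demonstrates that the architecture, losses,
training loop and explainability stack are implemented coherently — not
that the model reaches clinical-grade accuracy on real ultrasound.

## Scaled-down benchmark sizes

All heavy paths run on a **miniature** configuration chosen as the
package's CPU-scale reference: channels (8, 16, 32, 64), heads
(1, 2, 2, 4), d_state 8, one residual block per stage, 64×64 phantoms,
160 images in 2 image-disjoint folds, and a matching protocol
(lr 3·10⁻³, batch 8, ≤10 epochs, patience 8). On this benchmark the
2-fold held-out mean DSC is ≈0.90 and the run fits in minutes on one
CPU core. The reference (full-size) configuration is exercised
structurally (construction, parameter-count orderings) but not trained
in the test suite.

## Explainability layer

All attribution methods scalarize the dense output as the **sum of
logits over the predicted foreground** (all pixels when the prediction
is empty), with the predicted mask frozen while the input is perturbed.

* Grad-CAM++ (any recorded layer: per-branch features at 4 levels,
  fused maps, decoder nodes), Score-CAM (gradient-free channel
  scoring), Eigen-CAM (first singular component, sign-aligned,
  absolute value — exact |u| recovery on rank-1 activations).
* Integrated Gradients: midpoint-rule path integral. The default
  baseline is a Gaussian-blurred copy of the image (σ = 4), the same
  occlusion baseline as the superpixel methods: a zero image is far
  outside the normalized-speckle input distribution and the
  normalization layers' Jacobians spike near it (token variance
  collapses), which destroys quadrature convergence; with the blurred
  baseline the 256-step completeness axiom holds on the trained
  miniature model. An explicit zero baseline remains available.
* Kernel SHAP and LIME over SLIC superpixels (grid-seeded region growth
  on intensity); occluded segments are replaced by the blurred image;
  SHAP solves a Shapley-kernel-weighted least squares (empty/full
  coalitions anchored with weight 10⁷) and reproduces exact Shapley
  values on additive targets under exhaustive sampling; LIME is a
  ridge fit with an exponential proximity kernel.
* Attention rollout: per level, head-averaged attention mixed with
  identity ((A+I)/2); coarser matrices are expanded to the finest token
  grid (uniform over subdivided tokens, rows stay stochastic) and
  multiplied shallow→deep; rows of predicted-foreground tokens are
  averaged.
* MC-dropout uncertainty: T = 30 stochastic passes with only the
  dropout layers active (normalization stays in evaluation mode);
  per-pixel SD of sigmoid probabilities (≤ 0.5 by construction).
* Architectural XAI: branch deactivation (fusion logit pinned to −∞,
  softmax renormalizes; ΔDSC reported), per-level fusion-weight
  profiles, decoder-node activation maps.

Quantitative validation: nEAR (attribution energy fraction inside the
mask over the mask area fraction; energy = Σ|attr| so signed maps are
handled), top-k% hit rates (row-major tie-break), cross-method Spearman
and SSIM (window 7, maps min–max normalized, symmetric matrices),
pooled and per-image Pearson correlation between uncertainty and the
prediction-error indicator, error/correct and boundary/interior
uncertainty ratios with Cohen's d, DSC-quartile case selection
(duplicate ranks advance to the next unused rank so the four cases are
distinct), and mean-uncertainty failure flagging.

## Numerical and engineering choices

* The network and training loop run on a package-internal reverse-mode
  autodiff core over numpy (im2col convolution, batched matmul
  attention, a selective-scan primitive whose backward is the exact
  reverse-time adjoint recurrence). Gradients are verified against
  central finite differences in float64 throughout the test suite.
* Parameters are float32; XAI checks that need tighter arithmetic cast
  the model to float64.
* Wilcoxon signed-rank p-values are exact for n ≤ 25 (zeros dropped);
  the Friedman statistic uses the plain rank-sum formula (average ranks
  on ties, no tie correction) with a χ² reference distribution.
* Empty-mask metric conventions: both masks empty → DSC = IoU =
  B-IoU = 1, HD95 = 0; exactly one empty → 0s and the image diagonal as
  the HD95 sentinel (flagged in the record).
* Prediction threshold 0.5 on the sigmoid; HD95 boundary extraction
  uses 4-connectivity with image-border pixels counted as boundary;
  percentiles are linearly interpolated; HD95 is the max of the two
  directed 95th percentiles.
* Determinism: one seed drives parameter init, batch order,
  augmentation and dropout; training histories and reports are
  byte-identical across re-runs on a single CPU worker.

## Known limitations

* Phantoms are a first-order appearance model; no claim transfers to
  real BUS data without retraining and validation.
* The reference-scale model is not trained in-repo (CPU budget); only
  structural properties are asserted at that scale.
* The CNN anchor means auxiliary-branch deactivation measures the
  fusion-level contribution, not a fully independent branch.
* Attention rollout assumes the factorized positional embeddings keep
  token geometry consistent across levels; it is a qualitative method.
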