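# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phasedprior`. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is imported
from elsewhere.

## Forward model and conventions

The encoding operator is `y_j = M ⊙ F(x ⊙ c_j)` per coil, with a centered
unitary 2-D FFT (DC at index `n//2`, shift–transform–shift), so Parseval and
the adjoint identity hold to machine precision and all normalizations are
scale-free. Images are square, indexed `(row, col) = (phase-encode,
frequency-encode)`, 0-based. k-space containers enforce zeros off the
sampling mask on construction.

Two complex-Gaussian conventions coexist and are deliberate:

* **Measurement noise** of std `s` has real/imag components of std `s/√2`
  (`E|z|² = s²`) — the natural convention for k-space noise power.
* **Diffusion noise** `x_i = x_0 + σ_i ζ` uses `ζ` with real/imag components
  of std 1, so that a centered complex Gaussian prior of scale `s` (real and
  imaginary parts each `N(0, s²)`) has score exactly `−x/s²`. Under this
  convention the zero-model denoising loss per scale equals `2 n²` (the
  number of real degrees of freedom), which the tests verify against the
  analytic expectation.

## Synthetic data

The generator stands in for brain MR images at desk scale:

* **Phantoms**: random, partially overlapping ellipses (Shepp–Logan-like),
  clipped non-negative, normalized to max 1. Default 64×64; all operators
  are size-generic. Piecewise-constant content makes the ℓ1-wavelet baseline
  *stronger* than on real anatomy, so comparative results against it are
  conservative.
* **Phase**: smooth fields, either low-order random polynomials or Gaussian
  random fields with correlation length `n/4` and peak amplitude π/2 —
  mimicking receive-field and B0-inhomogeneity phase, which varies slowly.
* **Coils**: Gaussian-profile magnitude bumps centered on a ring outside the
  FOV with smooth low-order phase, normalized to root-sum-of-squares 1 at
  the image center — a surface-coil-array caricature.
* **Noise**: complex Gaussian in k-space at every sampled position.

What the generator does **not** emulate: anatomical texture, bias fields,
off-resonance/chemical-shift physics, partial-Fourier phase asymmetries,
coil noise correlations. Passing tests therefore demonstrate algorithmic
correctness and the claimed method ordering under idealized piecewise-smooth
images, not clinical image quality.

## Preprocessing pipeline

Magnitude volumes are (i) resampled in-plane to a square target size with
linear interpolation (preserves non-negativity; through-plane axis located
by its S/I orientation label), (ii) split into axial slices, (iii) given
background Gaussian noise (μ=0.003, σ=5 in raw intensity units, clipped at
zero) and normalized by their maximum, (iv) summarized by mean/std over a
30×30 corner patch (scaled proportionally below 256), and (v) excluded when
**both** μ < 0.04 **and** σ < 0.0061 (content-free slices; an `or` switch
exists for sensitivity analysis). The noise std is interpreted in raw
pre-normalization units: σ=5 on a max-1 image would destroy all content.
The patch anchor is the (0,0) corner (background in conformed brain
volumes); the std uses the population convention. The pipeline is a pure
function of (volume, seed).

## Noise schedule

`σ_i = σ_min + (σ_max−σ_min)·log(1 + (1−i/N)(e−1))`, i = 0…N, natural log;
defaults σ_max = 0.3, σ_min = 0.01 in units of max-1 image intensity. The
endpoints are analytically exact. Reverse-transition stds use the SMLD
ancestral variance `τ_i² = σ_{i+1}²(σ_i²−σ_{i+1}²)/σ_i²`.

## Priors

**Autodiff engine.** Both networks are implemented in NumPy over a small
tape-based reverse-mode autodiff module (broadcasted arithmetic, elementwise
nonlinearities, log-sum-exp, im2col convolution, gather; Adam optimizer).
Gradients are verified against central finite differences.

**PixelCNN.** A causal CNN (5×5 mask-A layer excluding the current pixel,
then 3×3 mask-B layers) predicts, per pixel, a K=5 logistic mixture over
256 bins on [−1, 1] per channel; the imaginary channel's mixture means
depend linearly on the observed real value (coefficient squashed by tanh).
Extreme bins use open logistic tails so each pixel's discretized
distribution sums to one exactly (verified by brute force over all 256×256
joint bins to 1e−6). Causality is verified by gradient probes: parameters
at pixel i have exactly zero gradient w.r.t. pixels ≥ i in raster order.
Log-scales are bounded below at e^−7 via a softplus reparameterization.
Magnitude-only (1-channel) mode supports priors trained without phase.

**Score network.** `s_θ(x, i) = g_i · f_θ(x) / σ_i` with `f_θ` a small conv
stack (3×3 kernels, ELU, default width 16–24, 3–4 layers) and one learned
scalar gain `g_i` per scale. Dividing by `σ_i` is the standard noise
conditioning (the network predicts the unit noise); the per-scale gain
absorbs the residual σ-dependence — for Gaussian data the representation
contains the analytic smoothed score `−x/(s²+σ_i²)` exactly, which training
recovers to < 0.25 relative L2 error at every scale (the residual floor is
dominated by zero-padding boundary effects of the convolutions). Training
minimizes the denoising score-matching loss with weights `λ_i = σ_i²`
(equivalently `‖σ_i s_θ + ζ‖²`), one uniformly drawn scale per batch
element, dihedral (mirror/flip/rotate) augmentation, Adam. After training
the per-scale gains are refit in closed form (`g* = −E⟨f, ζ⟩ / E‖f‖²` per
scale, a scalar least-squares problem given the frozen features): the
near-zero gains of the smallest scales converge slowly and noisily under
stochastic optimization alone. Float32 parameters; everything is a pure
function of the seed.

## Phase augmentation

Chains are initialized with complex Gaussian noise at scale σ_0 and run K
unadjusted Langevin steps per scale with step `γ_i = γ·σ_i²` and likelihood
gradient `2ε_i(m−|x|)·x/|x|` (|x| regularized by δ=1e−8). The likelihood
precision is annealed as `ε_i = ε/σ_i²`, which keeps the likelihood-step
prefactor `γ·ε` constant: the original formulation with constant ε is
unstable at large σ for any useful ε. Stability requires `γ·ε ≲ 1`.
Defaults ε=1, γ=0.5, K=5, n_samples=5. K controls phase mixing: with a
trained phantom prior, γ=0.8 and K=120 yield smooth phase robustly
(95th-percentile wrapped neighbour difference 0.14-0.20 rad on the signal
support across trained priors) at median magnitude deviation < 0.01;
small K leaves the phase under-mixed (rough, noise-like phase). Chains are
independently initialized (whether the original procedure shared
initializations is unknown; independence maximizes phase diversity).

## PICS

FISTA on `½‖F_c x − y‖² + αR(x)` with the data scaled on entry so the
zero-filled adjoint image has max magnitude 1 (the training normalization),
step size `0.95/L` from 10 power iterations on `F_cᴴF_c`, adaptive restart,
and — for the convex regularizers — the monotone FISTA variant, making the
objective non-increasing by construction. Proximal maps: ℓ2 (about zero)
closed form; ℓ1-wavelet = complex soft-thresholding of db4 periodized
wavedec2 detail coefficients (approximation band untouched); learned prior
= one gradient step `z + t·score(z, i)` with the scale index i advancing
with the iteration counter (i=0 first iteration, i=N last) and weight
`t = α·σ_i²` — a fraction α of the full Tweedie denoising step, decoupled
from the data-term step size. PICS-ℓ2 agrees with a conjugate-gradient
solution of the normal equations to better than 1e−6 relative on all three
sampling regimes.

## NLINV

IRGNM on `F(x, c)` with the coil variable kept in the Sobolev-preconditioned
k-space domain `c_j = F⁻¹(w⁻¹ ⊙ ĉ_j)`, `w(k) = (1 + a‖k‖²/‖k_max‖²)^{b/2}`
(defaults a=220, b=16), so the coil penalty is a plain ℓ2 norm. Weights
`α_k = α₀ qᵏ`, `β_k = β₀ qᵏ` (defaults α₀=β₀=1, q=1/2, 10 Gauss–Newton
steps, 5 of them stage 1). Design choices that proved necessary:

* **Anchored ℓ2.** The ℓ2 stages regularize toward the initialization
  (x=1, ĉ=0). Regularizing toward zero deadlocks the joint estimation:
  x→0 removes the coil derivative `F(x ⊙ δc)` and nothing can recover.
* **Block preconditioning.** Stage-2 FISTA uses separate step sizes for the
  image and coil blocks (each `0.95/(2·L_block)`; the factor 2 majorizes the
  cross terms). The coil block's curvature is orders of magnitude larger,
  and a single joint step size starves the image updates.
* **Prior in the coil-combined frame.** The (x, c) factorization pushes coil
  shading into x, which the prior never saw in training; the prox is
  therefore applied to `x·rss(c)` normalized to max 1, and mapped back with
  a floor of 0.05·max on rss. The stage-2 annealing starts at a
  configurable fraction of the schedule (default 0.7) since the image is
  already partially converged after stage 1, and the prior weight
  `t = w·σ_i²` (default w=0.02) is decoupled from the decaying α_k — the
  advancing scale index plays that role.
* Sub-problems are warm-started; stage-2 FISTA runs concatenate for the
  scale indexing.

Accuracy on noiseless data is limited by the α/β floor and the coil
passband, not the inner solvers: the default 10 steps reach ≈5e−2 relative
coil-product error, while 22 steps with q=0.35 and Sobolev order b=8
reach 3e−3 to 7e−3 across coil realizations (the configuration used in
the recovery checks). At small grids the coil spectrum occupies
relatively more of k-space, which is why the recovery checks relax the
Sobolev order. The solver output `x·rss(c)` is the scale-invariant image
used for metrics.

## Masks

1-D: every accel-th phase-encode line, anchored through the center, plus a
fully sampled centered calibration block. Grid: offsets mod (ax, ay)
through the center plus calibration. Poisson-disc: dart throwing on the
integer grid with rejection radius tuned by up to 14 bisection steps to hit
the target acceleration within ±10%; **variable density by default** (local
radius `r·(0.5 + |k|/k_max)`), because with uniform density the jamming
densities on a small integer grid are quantized and intermediate
accelerations (e.g. 8.2 at n=64) are unreachable. The pairwise distance
between any two accepted points outside calibration is at least the smaller
of their local radii (verified by an O(n⁴) pair scan).

## Coil calibration

A low-resolution estimate replaces eigenvector-based calibration: the fully
sampled central block is Hann-apodized, zero-padded, inverse-transformed,
and divided by the root-sum-of-squares across coils with relative
regularization 1e−3. The estimate is scale-invariant and accurate on the
interior of the object support; it cannot resolve the support edges (its
resolution is the calibration width), which is why the recovery check
compares on the eroded support. An externally computed map can be injected
everywhere a `CoilSensitivities` is accepted.

## Metrics and harness

PSNR `10·log₁₀(peak²/MSE)` on magnitudes, peak = max of the reference,
capped at 150 dB for identical inputs. SSIM with the standard 11×11
Gaussian window (σ=1.5), C₁=(0.01L)², C₂=(0.03L)², L = reference max,
population covariance, edge strip cropped — written independently and
cross-checked against scikit-image to 1e−6. The retrospective harness
reconstructs a seeded phantom over a methods × regularizers × masks grid
against the coil-combined fully sampled reference and reproduces its CSV
bit-for-bit from config + seed. Robustness statistics compare
higher-acceleration reconstructions against a low-acceleration
reconstruction per slice, with 1.5·IQR boxplot fences for outlier counts.

## Problem sizes

Chosen as the package's own desk-scale defaults: priors train at 64×64 on
~100 phantoms for 1500 SMLD steps (≈8 min on one CPU); score-recovery
checks use 16×16 Gaussian images (2500 steps); solver-equivalence checks
run at 128×128 with the standard mask parameters (5× + 30 calibration
lines, 2×3 grid, Poisson-disc 8.2× with a 30×25 center); end-to-end
comparisons use 64×64, 8 coils, ≈4× variable-density Poisson-disc.

## Known limitations

* The priors are far smaller than production diffusion/autoregressive
  models; they demonstrate the workflow, not attainable image quality.
* The one-step proximal approximation is first-order: its O(t²) error is
  verified against the exact Gaussian prox, but for strongly multimodal
  priors a multi-step prox could behave differently.
* NLINV coil bandwidth is bounded by the Sobolev penalty and the β floor;
  coil arrays with sharp spatial features would need retuned (a, b).
* PixelCNN likelihood evaluation is exact but O(n²) per gradient call,
  which is why the reconstruction experiments use the score prior.
* The nonlinear real↔imaginary dependency variant of the autoregressive
  likelihood is left as a config hook; only the linear dependence is
  implemented.
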