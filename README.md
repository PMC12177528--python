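# phasedprior

Generative image priors for compressed-sensing parallel MRI, trained from
**magnitude-only** images via **phase augmentation**, and used as plug-in
proximal regularizers in linear (PICS) and nonlinear (NLINV) reconstruction.

## The problem

Accelerated MRI acquires undersampled multi-coil k-space data

```
y_j = F_S(x ⊙ c_j) + noise,     j = 1 … nc
```

where `x ∈ C^{n×n}` is the complex image, `c_j` the coil sensitivity maps and
`F_S` the undersampled (centered, unitary) Fourier transform. Reconstruction
solves either the linear problem with pre-estimated coils,

```
min_x  ½‖F_c(x) − y‖² + α R(x)             (PICS, solved by FISTA)
```

or jointly estimates image and coils by the iteratively regularized
Gauss–Newton method,

```
min_δm ½‖F'(m_k)δm + F(m_k) − y‖² + β_k W(c_k+δc) + α_k R(x_k+δx)   (NLINV)
```

with a Sobolev penalty `W(c) = ‖w ⊙ Fc‖²` keeping the coils smooth and
`α_k, β_k` decaying geometrically.

The regularizer `R` can be classical (ℓ2, ℓ1-wavelet) or a **learned
log-prior** of complex images, applied through the one-gradient-step proximal
approximation `prox_t(z) ≈ z + t ∇_x log p(z)`. Two generative priors are
implemented from scratch (in NumPy, on a small reverse-mode autodiff engine):

* an autoregressive **PixelCNN** with a discretized logistic-mixture
  likelihood per pixel (two channels: real and imaginary, with a linear
  cross-channel dependence), and
* a **score network** trained by denoising score matching (SMLD) over the
  noise schedule `σ_i = σ_min + (σ_max−σ_min)·log(1 + (1−i/N)(e−1))`,
  `σ_max = 0.3`, `σ_min = 0.01`.

Because most public MR image archives store magnitude only, complex-valued
training data is produced by **phase augmentation**: annealed unadjusted
Langevin sampling of the posterior `p(x|m) ∝ p(x)·exp(−ε‖m − |x|‖²)` under a
complex-image prior, which keeps the magnitude close to `m` while the prior
generates a smooth, realistic phase.

All stages run at desk scale on synthetic data: random ellipse phantoms with
smooth synthetic phase, smooth complex coil maps, and the standard sampling
regimes (1-D equispaced + calibration lines, 2×3 grid, variable-density
Poisson-disc).

## Worked example

```python
import numpy as np
from phasedprior import *
from phasedprior.types import SamplingMask
from phasedprior.operators import estimate_coils_calib, apply_adjoint

# simulate an 8-coil acquisition of a 64x64 complex phantom at ~4x
truth = make_complex_phantom(n=64, seed=7)
coils = make_coil_maps(64, 8, seed=8)
mask  = make_mask_poisson(64, target_accel=4.0, calib=(16, 14), seed=5)
y     = simulate_kspace(truth, coils, mask, noise_std=0.005, seed=9)

# reference: coil-combined fully sampled reconstruction
full   = SamplingMask(np.ones((64, 64), dtype=bool))
y_full = simulate_kspace(truth, coils, full, noise_std=0.005, seed=9)
ref    = apply_adjoint(y_full, estimate_coils_calib(y_full, calib_region=16))

# train a score prior on phantoms, then reconstruct
data = [d.data for d in make_dataset(96, n=64, seed=100)]
sch  = build_schedule(N=10)
prior, _ = train_score_net(data, sch, ScoreNetConfig(width=24, n_layers=4),
                           steps=1500, seed=0)

coils_est = estimate_coils_calib(y, calib_region=(16, 14))
for reg, alpha in [("l2", 0.02), ("l1wav", 0.002), ("prior", 0.15)]:
    cfg = PicsConfig(regularizer=reg, alpha=alpha, iters=100)
    res = PicsModel(y, coils_est, cfg,
                    prior=prior if reg == "prior" else None,
                    schedule=sch if reg == "prior" else None).fit()
    print(f"PICS {reg:6s}  PSNR {psnr(ref, res.image):5.2f} dB"
          f"  SSIM {ssim(ref, res.image):.4f}")
```

Output (one CPU, ~10 min including training):

```
PICS l2      PSNR 34.27 dB  SSIM 0.7098
PICS l1wav   PSNR 42.46 dB  SSIM 0.9551
PICS prior   PSNR 44.06 dB  SSIM 0.9747
```

The learned score prior removes the incoherent aliasing of the 4×
undersampling better than both classical regularizers; the same ordering
holds for NLINV (`NlinvModel(y, NlinvConfig(regularizer="prior", ...))`,
whose `fit()` additionally returns the jointly estimated coil maps).
`res.summary()` prints the solver diagnostics.

A command-line interface mirrors the library:

```sh
phasedprior simulate --n 64 --nc 8 --accel 4 --out sim/
phasedprior train-prior --type score --channels 2 --out ckpt
phasedprior pics --kspace sim/kspace --mask sim/mask --reg prior \
            --prior ckpt --out recon
phasedprior evaluate --n 64 --out report/
```

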