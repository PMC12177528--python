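"""Image-quality metrics: PSNR and SSIM on magnitude images.

Both metrics compare magnitude images (the phase is evaluated
qualitatively elsewhere); the PSNR peak and the SSIM data range use the
reference maximum.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import ComplexImage

__all__ = ["psnr", "ssim", "PSNR_CAP"]

PSNR_CAP = 150.0  # sentinel reported for identical images (dB)


def _mag(x) -> np.ndarray:
    if isinstance(x, ComplexImage):
        return x.magnitude()
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else x.astype(np.float64)


def psnr(ref, test) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB.

    Computed on magnitudes with peak = max |ref|. Identical inputs return
    the cap sentinel ``PSNR_CAP``.
    """
    r, t = _mag(ref), _mag(test)
    if r.shape != t.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((r - t) ** 2))
    peak = float(r.max())
    if mse == 0:
        return PSNR_CAP
    if peak == 0:
        raise ValueError("reference image is empty")
    return min(10.0 * np.log10(peak**2 / mse), PSNR_CAP)


def ssim(ref, test, sigma: float = 1.5, truncate: float = 3.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity index on magnitude images.

    Standard definition: local means/variances/covariance from an 11x11
    Gaussian window (sigma = 1.5, i.e. truncation at 3.5 sigma),
    C1 = (k1 L)^2 and C2 = (k2 L)^2 with data range L = max |ref|.
    """
    r, t = _mag(ref), _mag(test)
    if r.shape != t.shape:
        raise ValueError("shape mismatch")
    L = float(r.max())
    if L == 0:
        raise ValueError("reference image is empty")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2

    def filt(a):
        return gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    mu_r, mu_t = filt(r), filt(t)
    var_r = filt(r * r) - mu_r**2
    var_t = filt(t * t) - mu_t**2
    cov = filt(r * t) - mu_r * mu_t
    num = (2 * mu_r * mu_t + c1) * (2 * cov + c2)
    den = (mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2)
    s = num / den
    pad = int(truncate * sigma + 0.5)  # drop the edge strip the window touches
    return float(np.mean(s[pad:-pad, pad:-pad]))
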