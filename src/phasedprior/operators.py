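"""Parallel-imaging encoding operator, sampling masks and coil calibration.

The forward model maps an image ``x`` and coil maps ``c`` to multi-coil
k-space: ``y_j = mask * FFT(x * c_j)`` with a centered, unitary 2-D FFT
(DC at index n//2; Parseval holds exactly), so adjoint and normalization
tests are scale-free.
"""

from __future__ import annotations

import numpy as np

from .types import ComplexImage, CoilSensitivities, KSpace, SamplingMask

__all__ = [
    "fft2c",
    "ifft2c",
    "apply_forward",
    "apply_adjoint",
    "make_mask_1d",
    "make_mask_grid",
    "make_mask_poisson",
    "estimate_coils_calib",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D FFT over the first two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


def apply_forward(
    x: ComplexImage | np.ndarray,
    c: CoilSensitivities,
    mask: SamplingMask,
) -> KSpace:
    """Encoding operator ``F(x, c) = (mask * FFT(x*c_1), ..., mask * FFT(x*c_nc))``."""
    xd = x.data if isinstance(x, ComplexImage) else np.asarray(x)
    if c.spatial_shape != xd.shape:
        raise ValueError("image / coil shape mismatch")
    coil_imgs = xd[:, :, None] * c.data
    y = fft2c(coil_imgs) * mask.data[:, :, None]
    return KSpace(y, mask)


def apply_adjoint(y: KSpace, c: CoilSensitivities) -> ComplexImage:
    """Adjoint operator ``F^H(y) = sum_j conj(c_j) * IFFT(y_j)``."""
    if c.data.shape != y.data.shape:
        raise ValueError("k-space / coil shape mismatch")
    imgs = ifft2c(y.data)
    x = np.sum(np.conj(c.data) * imgs, axis=2)
    return ComplexImage(x, meta={"source": "adjoint"})


def _calib_block(n: int, size: int) -> slice:
    """Centered index range of ``size`` positions on an axis of length n."""
    size = min(size, n)
    start = n // 2 - size // 2
    return slice(start, start + size)


def make_mask_1d(n: int, accel: int = 5, calib_lines: int = 30) -> SamplingMask:
    """1-D undersampling: every ``accel``-th phase-encode line plus a fully
    sampled centered calibration block of ``calib_lines`` lines.

    The regular pattern is anchored so that it passes through the center
    line (symmetric about DC).
    """
    if accel < 1:
        raise ValueError("accel must be >= 1")
    if calib_lines > n:
        raise ValueError("calib_lines cannot exceed n")
    mask = np.zeros((n, n), dtype=bool)
    offset = (n // 2) % accel  # pattern passes through the center line
    mask[offset::accel, :] = True
    mask[_calib_block(n, calib_lines), :] = True
    return SamplingMask(mask, info={"type": "1d", "accel": accel, "calib": calib_lines})


def make_mask_grid(
    n: int, ax: int = 2, ay: int = 3, calib: int | tuple[int, int] = 0
) -> SamplingMask:
    """Regular 2-D grid undersampling by factors (ax, ay) along
    (frequency, phase) = (column, row), plus an optional centered
    calibration block."""
    if ax < 1 or ay < 1:
        raise ValueError("accelerations must be >= 1")
    mask = np.zeros((n, n), dtype=bool)
    roff = (n // 2) % ay
    coff = (n // 2) % ax
    mask[roff::ay, coff::ax] = True
    if calib:
        cy, cx = (calib, calib) if np.isscalar(calib) else calib
        mask[_calib_block(n, cy), _calib_block(n, cx)] = True
    return SamplingMask(mask, info={"type": "grid", "ax": ax, "ay": ay, "calib": calib})


def poisson_radius_at(py: int, px: int, n: int, r: float,
                      variable_density: bool) -> float:
    """Local rejection radius: constant, or growing with |k| so sampling
    is denser near the k-space center (variable density)."""
    if not variable_density:
        return r
    center = (n - 1) / 2
    dist = float(np.hypot(py - center, px - center)) / (n / 2)
    return r * (0.5 + dist)


def _poisson_mask_for_radius(
    n: int, r: float, calib: tuple[int, int], rng: np.random.Generator,
    variable_density: bool,
) -> np.ndarray:
    """Dart throwing on the integer grid: a candidate is accepted if no
    previously accepted point lies within its local rejection radius."""
    mask = np.zeros((n, n), dtype=bool)
    cy, cx = calib
    calib_ry = _calib_block(n, cy)
    calib_rx = _calib_block(n, cx)
    # precomputed disk templates per integer reach
    templates: dict[int, np.ndarray] = {}
    order = rng.permutation(n * n)
    for idx in order:
        py, px = int(idx // n), int(idx % n)
        if calib_ry.start <= py < calib_ry.stop and calib_rx.start <= px < calib_rx.stop:
            continue
        rr = poisson_radius_at(py, px, n, r, variable_density)
        reach = int(np.ceil(rr)) - 1 if rr == int(rr) else int(np.floor(rr))
        reach = max(reach, 0)
        if reach not in templates:
            d = np.arange(-reach, reach + 1)
            templates[reach] = (d[:, None] ** 2 + d[None, :] ** 2)
        y0, y1 = max(0, py - reach), min(n, py + reach + 1)
        x0, x1 = max(0, px - reach), min(n, px + reach + 1)
        tpl = templates[reach][
            y0 - (py - reach) : y1 - (py - reach),
            x0 - (px - reach) : x1 - (px - reach),
        ]
        if np.any(mask[y0:y1, x0:x1] & (tpl < rr * rr)):
            continue
        mask[py, px] = True
    mask[calib_ry, calib_rx] = True
    return mask


def make_mask_poisson(
    n: int,
    target_accel: float = 8.2,
    calib: int | tuple[int, int] = (30, 25),
    seed: int = 0,
    variable_density: bool = True,
    tol: float = 0.10,
) -> SamplingMask:
    """Poisson-disc sampling mask hitting ``target_accel`` within ``tol``.

    Dart throwing with the rejection radius tuned by bisection until the
    achieved acceleration n^2 / (#samples) is within the tolerance of the
    target. The centered calibration block is always fully sampled.
    Deterministic given the seed.
    """
    if target_accel < 1:
        raise ValueError("target_accel must be >= 1")
    cy, cx = (calib, calib) if np.isscalar(calib) else calib
    cy, cx = min(cy, n), min(cx, n)
    budget = n * n / target_accel
    if cy * cx > budget:
        raise ValueError(
            f"calibration block {cy}x{cx} alone exceeds the sample budget "
            f"{budget:.0f} for target acceleration {target_accel}"
        )
    if target_accel == 1.0:
        return SamplingMask(np.ones((n, n), dtype=bool), info={"type": "poisson", "accel": 1.0})

    lo, hi = 0.5, float(n)
    best = None
    for it in range(14):
        r = 0.5 * (lo + hi)
        rng = np.random.default_rng(seed)  # same darts each trial radius
        mask = _poisson_mask_for_radius(n, r, (cy, cx), rng, variable_density)
        accel = n * n / mask.sum()
        if best is None or abs(accel - target_accel) < abs(best[1] - target_accel):
            best = (mask, accel, r)
        if abs(accel - target_accel) / target_accel <= tol / 2:
            break
        if accel > target_accel:
            hi = r  # too sparse -> shrink radius
        else:
            lo = r
    mask, accel, r = best
    if abs(accel - target_accel) / target_accel > tol:
        raise RuntimeError(
            f"could not reach target acceleration {target_accel} "
            f"(achieved {accel:.2f})"
        )
    return SamplingMask(
        mask,
        info={
            "type": "poisson",
            "target_accel": target_accel,
            "achieved_accel": accel,
            "min_dist": r,
            "calib": (cy, cx),
            "seed": seed,
            "variable_density": variable_density,
        },
    )


def estimate_coils_calib(
    y: KSpace,
    calib_region: int | tuple[int, int] = 30,
    reg: float = 1e-3,
) -> CoilSensitivities:
    """Low-resolution coil sensitivity estimate from the calibration region.

    Per coil: extract the fully sampled centered calibration block, apodize
    it with a Hann window, zero-pad back to the full grid and inverse-FFT;
    the maps are these low-resolution coil images divided by their
    root-sum-of-squares (regularized). The result is smooth, has
    root-sum-of-squares ~= 1 where signal exists, and is invariant to a
    global k-space scale.
    """
    n = y.data.shape[0]
    cy, cx = (calib_region, calib_region) if np.isscalar(calib_region) else calib_region
    ry, rx = _calib_block(n, cy), _calib_block(n, cx)
    block = y.data[ry, rx, :]
    wy = np.hanning(block.shape[0] + 2)[1:-1]
    wx = np.hanning(block.shape[1] + 2)[1:-1]
    apod = wy[:, None] * wx[None, :]
    padded = np.zeros_like(y.data)
    padded[ry, rx, :] = block * apod[:, :, None]
    lowres = ifft2c(padded)
    rss = np.sqrt(np.sum(np.abs(lowres) ** 2, axis=2))
    scale = rss.max()
    if scale == 0:
        raise ValueError("calibration region contains no signal")
    maps = lowres / (rss[:, :, None] + reg * scale)
    return CoilSensitivities(maps)
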