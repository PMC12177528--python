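"""Synthetic phantoms, smooth phase fields, coil maps and noisy k-space.

These generators emulate the statistical structure the reconstruction
pipeline assumes about brain MRI data: piecewise-smooth magnitude images
(random ellipse phantoms), smooth slowly-varying phase (receive-field and
B0-inhomogeneity phase is smooth in practice), smooth complex coil
sensitivities, and complex Gaussian measurement noise in k-space.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ComplexImage, CoilSensitivities, KSpace, SamplingMask

__all__ = [
    "PhantomSpec",
    "PhaseFieldSpec",
    "make_phantom",
    "make_phase_field",
    "make_coil_maps",
    "simulate_kspace",
    "make_complex_phantom",
    "make_dataset",
]


@dataclass
class PhantomSpec:
    """Parameters for a random-ellipse phantom (Shepp-Logan-like)."""

    n: int = 64
    n_ellipses: int = 8
    intensity_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("n must be at least 8")
        if self.intensity_range[0] < 0:
            raise ValueError("intensity lower bound must be >= 0")


@dataclass
class PhaseFieldSpec:
    """Parameters for a smooth synthetic phase map.

    ``kind='polynomial'`` gives a low-order 2-D polynomial in normalized
    coordinates; ``kind='gaussian-random-field'`` gives a Gaussian random
    field with the stated correlation length (pixels), rescaled to the
    stated peak amplitude (radians).
    """

    kind: str = "gaussian-random-field"
    order: int = 2
    correlation_length: float = 16.0
    amplitude: float = np.pi / 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "gaussian-random-field"):
            raise ValueError(f"unknown phase field kind {self.kind!r}")
        if not 0 <= self.amplitude <= np.pi:
            raise ValueError("amplitude must lie in [0, pi]")


def make_phantom(spec: PhantomSpec) -> ComplexImage:
    """Random overlapping-ellipse phantom, normalized to max value 1.

    Returns a real-valued (zero-phase) :class:`ComplexImage`. With
    ``n_ellipses=0`` the image is identically zero.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    yy, xx = np.mgrid[0:n, 0:n]
    yy = (yy - (n - 1) / 2) / (n / 2)
    xx = (xx - (n - 1) / 2) / (n / 2)
    img = np.zeros((n, n))
    lo, hi = spec.intensity_range
    for _ in range(spec.n_ellipses):
        cx, cy = rng.uniform(-0.55, 0.55, size=2)
        a = rng.uniform(0.12, 0.55)
        b = rng.uniform(0.12, 0.55)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0], p=[0.25, 0.75])
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img += amp * ((u / a) ** 2 + (v / b) ** 2 <= 1.0)
    img = np.clip(img, 0, None)
    m = img.max()
    if m > 0:
        img /= m
    return ComplexImage(img.astype(np.complex128), meta={"seed": spec.seed, "source": "phantom"})


def make_phase_field(spec: PhaseFieldSpec, n: int) -> np.ndarray:
    """Smooth 2-D phase map in radians, values in (-pi, pi].

    The polynomial variant evaluates a random polynomial of the stated
    order on [-1, 1]^2 coordinates; the random-field variant low-pass
    filters white noise with a Gaussian kernel of the stated correlation
    length. Both are rescaled so the peak absolute value equals the
    amplitude.
    """
    if spec.amplitude == 0:
        return np.zeros((n, n))
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:n, 0:n]
    yy = (yy - (n - 1) / 2) / (n / 2)
    xx = (xx - (n - 1) / 2) / (n / 2)
    if spec.kind == "polynomial":
        field = np.zeros((n, n))
        for p in range(spec.order + 1):
            for q in range(spec.order + 1 - p):
                field += rng.normal() * xx**p * yy**q
    else:
        # Gaussian random field: filter white noise in Fourier domain
        white = rng.normal(size=(n, n))
        ky = np.fft.fftfreq(n)[:, None]
        kx = np.fft.fftfreq(n)[None, :]
        ell = spec.correlation_length
        kernel = np.exp(-2 * (np.pi * ell) ** 2 * (kx**2 + ky**2))
        field = np.real(np.fft.ifft2(np.fft.fft2(white) * kernel))
    peak = np.abs(field).max()
    if peak > 0:
        field = field * (spec.amplitude / peak)
    return field


def make_coil_maps(n: int, nc: int, seed: int = 0, uniform: bool = False) -> CoilSensitivities:
    """Smooth complex coil sensitivity maps, shape ``n x n x nc``.

    Each coil is a Gaussian-shaped magnitude bump centered outside the FOV
    on a circle around the image (mimicking surface receive coils) with a
    smooth low-order phase. With ``uniform=True`` and ``nc=1`` the map is
    identically one. Maps are scaled so the root-sum-of-squares is close
    to one at the image center.
    """
    if nc < 1:
        raise ValueError("need at least one coil")
    if uniform:
        return CoilSensitivities(np.ones((n, n, nc), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    yy = (yy - (n - 1) / 2) / (n / 2)
    xx = (xx - (n - 1) / 2) / (n / 2)
    maps = np.empty((n, n, nc), dtype=np.complex128)
    for j in range(nc):
        ang = 2 * np.pi * j / nc + rng.uniform(-0.2, 0.2)
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        width = rng.uniform(1.0, 1.4)
        mag = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2))
        phase = (
            rng.uniform(-np.pi, np.pi)
            + rng.normal(scale=0.8) * xx
            + rng.normal(scale=0.8) * yy
            + rng.normal(scale=0.4) * xx * yy
        )
        maps[:, :, j] = mag * np.exp(1j * phase)
    rss_center = np.sqrt(np.sum(np.abs(maps[n // 2, n // 2, :]) ** 2))
    maps /= rss_center
    return CoilSensitivities(maps)


def simulate_kspace(
    x: ComplexImage,
    c: CoilSensitivities,
    mask: SamplingMask,
    noise_std: float = 0.0,
    seed: int = 0,
) -> KSpace:
    """Simulate undersampled multi-coil k-space measurements.

    Per coil j: ``y_j = mask * (centered unitary FFT(x * c_j) + noise)``
    with complex Gaussian noise whose real/imag components each have std
    ``noise_std / sqrt(2)`` (so E|z|^2 = noise_std^2) at every sampled
    position.
    """
    from .operators import apply_forward  # local import to avoid cycle

    if c.spatial_shape != x.data.shape or mask.data.shape != x.data.shape:
        raise ValueError("image / coil / mask shape mismatch")
    y = apply_forward(x, c, mask)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        s = noise_std / np.sqrt(2)
        noise = rng.normal(scale=s, size=y.data.shape) + 1j * rng.normal(
            scale=s, size=y.data.shape
        )
        return KSpace(y.data + noise * mask.data[:, :, None], mask)
    return y


def make_complex_phantom(
    n: int = 64,
    seed: int = 0,
    n_ellipses: int = 8,
    phase_amplitude: float = np.pi / 2,
) -> ComplexImage:
    """Ellipse phantom with a smooth random phase, max magnitude 1."""
    mag = make_phantom(PhantomSpec(n=n, n_ellipses=n_ellipses, seed=seed))
    ph = make_phase_field(
        PhaseFieldSpec(
            kind="gaussian-random-field",
            correlation_length=n / 4,
            amplitude=phase_amplitude,
            seed=seed + 1,
        ),
        n,
    )
    data = mag.data.real * np.exp(1j * ph)
    return ComplexImage(data, meta={"seed": seed, "source": "complex-phantom"})


def make_dataset(
    n_images: int,
    n: int = 64,
    seed: int = 0,
    complex_phase: bool = True,
) -> list[ComplexImage]:
    """A list of normalized phantom images for prior training.

    Each image has max magnitude exactly 1 (the training normalization
    convention) unless it is empty.
    """
    out = []
    for k in range(n_images):
        img = (
            make_complex_phantom(n=n, seed=seed + 1000 * k)
            if complex_phase
            else make_phantom(PhantomSpec(n=n, seed=seed + 1000 * k))
        )
        m = np.abs(img.data).max()
        if m > 0:
            img = ComplexImage(img.data / m, meta=img.meta)
        out.append(img)
    return out
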