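"""Phase augmentation: conditional generation of complex images from
magnitude-only images by annealed unadjusted Langevin dynamics.

Given a magnitude image m and a prior over complex images, samples are
drawn from the posterior p(x | m) proportional to p(x) exp(-eps ||m - |x|||^2)
by running K unadjusted Langevin steps at each noise scale of the
schedule, from sigma_max down to sigma_min. The magnitude of the result
stays close to m while the phase is generated by the prior (smooth, with
random variation between chains).

The likelihood precision is annealed as eps_i = epsilon / sigma_i^2 and
the step size as gamma_i = gamma * sigma_i^2, so the likelihood gradient
prefactor gamma_i * eps_i stays constant across scales (stability) while
the prior term dominates early and the data term late.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .priors import PriorModel
from .schedule import NoiseSchedule
from .types import ComplexImage

__all__ = ["AugmentConfig", "magnitude_loglik_grad", "noise_term", "augment_phase"]

_DELTA = 1e-8  # |x| -> sqrt(|x|^2 + delta^2) regularization


@dataclass
class AugmentConfig:
    """Langevin sampler settings.

    epsilon : base likelihood precision; effective precision at scale i is
        epsilon / sigma_i^2 (dimensionless, on max-1-normalized images).
    gamma : base step size; step at scale i is gamma * sigma_i^2.
    K : Langevin iterations per scale.
    n_samples : independent chains (augmented images) per magnitude input.
    """

    epsilon: float = 1.0
    gamma: float = 0.5
    K: int = 5
    n_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.gamma <= 0:
            raise ValueError("epsilon and gamma must be positive")
        if self.K < 1 or self.n_samples < 1:
            raise ValueError("K and n_samples must be >= 1")


def magnitude_loglik_grad(x: np.ndarray, m: np.ndarray, epsilon: float) -> np.ndarray:
    """Gradient of log p(m|x) = -eps ||m - |x|||^2 w.r.t. (x_r, x_i).

    Per pixel: 2 eps (m - |x|) x / |x|, with |x| regularized by
    sqrt(|x|^2 + delta^2) so the gradient is finite at x = 0.
    """
    x = np.asarray(x, dtype=np.complex128)
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("magnitude image must be non-negative")
    if x.shape != m.shape:
        raise ValueError("shape mismatch")
    mag = np.sqrt(np.abs(x) ** 2 + _DELTA**2)
    return 2.0 * epsilon * (m - mag) * x / mag


def noise_term(shape, gamma: float, seed: int = 0) -> np.ndarray:
    """sqrt(gamma)-scaled standard complex Gaussian draw.

    The unscaled draw is CN(0, 1): real/imag components each of std
    1/sqrt(2), so each component of the output has std sqrt(gamma/2).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return np.zeros(shape, dtype=np.complex128)
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(2.0)
    z = rng.normal(scale=s, size=shape) + 1j * rng.normal(scale=s, size=shape)
    return np.sqrt(gamma) * z


def augment_phase(
    m: np.ndarray | ComplexImage,
    prior: PriorModel,
    schedule: NoiseSchedule,
    cfg: AugmentConfig | None = None,
) -> list[ComplexImage]:
    """Generate complex images whose magnitude matches m.

    Each of the ``n_samples`` chains is initialized independently with
    complex Gaussian noise at scale sigma_0 and annealed through the
    schedule with K Langevin steps per scale:

        x <- x + (gamma_i/2) (score(x, i) + grad log p(m|x)) + noise_term

    Deterministic given cfg.seed; chain c uses sub-seeds derived from
    (seed, c).
    """
    cfg = cfg or AugmentConfig()
    md = m.magnitude() if isinstance(m, ComplexImage) else np.asarray(m, dtype=np.float64)
    if md.max() > 1.0 + 1e-6:
        raise ValueError("magnitude input must be normalized to max 1")
    n_scales = schedule.N + 1
    out = []
    for chain in range(cfg.n_samples):
        rng = np.random.default_rng((cfg.seed, chain))
        s0 = schedule[0] / np.sqrt(2.0)
        x = rng.normal(scale=s0, size=md.shape) + 1j * rng.normal(scale=s0, size=md.shape)
        for i in range(n_scales):
            sig = schedule[i]
            gamma_i = cfg.gamma * sig**2
            eps_i = cfg.epsilon / sig**2
            for _ in range(cfg.K):
                drift = prior.score(x, i) + magnitude_loglik_grad(x, md, eps_i)
                s = np.sqrt(gamma_i / 2.0)
                z = rng.normal(scale=s, size=md.shape) + 1j * rng.normal(
                    scale=s, size=md.shape
                )
                x = x + (gamma_i / 2.0) * drift + z
        out.append(ComplexImage(x, meta={"seed": cfg.seed, "chain": chain,
                                         "source": "phase-augmentation"}))
    return out
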