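"""Geometric-logarithmic noise schedule shared by training, phase
augmentation and reconstruction.

The schedule interpolates between sigma_max and sigma_min over N + 1
scales via

    sigma_i = sigma_min + (sigma_max - sigma_min) * log(1 + (1 - i/N) * (e - 1))

for i = 0..N (natural log, e = Euler's constant), so sigma_0 = sigma_max
and sigma_N = sigma_min exactly. Defaults sigma_max = 0.3, sigma_min = 0.01
in units of the max-1-normalized image intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "build_schedule", "tau_from_schedule", "TauSequence"]


@dataclass
class NoiseSchedule:
    sigma_min: float
    sigma_max: float
    N: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.N + 1,):
            raise ValueError("schedule must hold N + 1 values")
        if not np.all(np.diff(v) < 0):
            raise ValueError("schedule must be strictly decreasing")
        self.values = v

    def __len__(self) -> int:
        return self.N + 1

    def __getitem__(self, i: int) -> float:
        return float(self.values[i])


def build_schedule(sigma_min: float = 0.01, sigma_max: float = 0.3, N: int = 10) -> NoiseSchedule:
    """Build the log-interpolated noise schedule (see module docstring)."""
    if not 0 < sigma_min < sigma_max:
        raise ValueError("need 0 < sigma_min < sigma_max")
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(N + 1, dtype=np.float64)
    values = sigma_min + (sigma_max - sigma_min) * np.log1p((1.0 - i / N) * (np.e - 1.0))
    return NoiseSchedule(sigma_min=sigma_min, sigma_max=sigma_max, N=N, values=values)


@dataclass
class TauSequence:
    """Reverse-transition noise stds tau_i, one per step i = 0..N-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < 0):
            raise ValueError("tau must be non-negative")
        self.values = v


def tau_from_schedule(schedule: NoiseSchedule) -> TauSequence:
    """Ancestral-sampling transition stds for the SMLD reverse process:

        tau_i^2 = sigma_{i+1}^2 (sigma_i^2 - sigma_{i+1}^2) / sigma_i^2.

    For a strictly decreasing schedule every tau_i > 0; equal consecutive
    sigmas would give tau = 0 (degenerate, rejected at schedule build).
    """
    s = schedule.values
    tau2 = s[1:] ** 2 * (s[:-1] ** 2 - s[1:] ** 2) / s[:-1] ** 2
    return TauSequence(np.sqrt(np.maximum(tau2, 0.0)))
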