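"""Core array containers for the reconstruction pipeline.

The central objects are a complex-valued image slice ``x``, per-coil complex
sensitivity maps ``c`` and undersampled multi-coil k-space data ``y`` related
by the parallel-imaging forward model ``y_j = F_S(x * c_j)``.

Conventions
-----------
* Images are square ``n x n``, indexed ``(row, column)`` =
  (phase-encode, frequency-encode), 0-based.
* k-space arrays use the centered convention: DC at index ``n // 2`` on each
  axis, consistent with a shift-transform-shift FFT.
* Coil arrays are ``n x n x nc`` with the coil axis last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MagnitudeVolume",
    "ComplexImage",
    "CoilSensitivities",
    "SamplingMask",
    "KSpace",
]


@dataclass
class MagnitudeVolume:
    """A 3-D non-negative magnitude volume (e.g. loaded from NIfTI).

    Parameters
    ----------
    data : ndarray
        Non-negative real intensities, three spatial dimensions.
    voxel_size : tuple of float
        Voxel edge length in mm per axis.
    orientation : tuple of str
        Axis codes (e.g. ``('R', 'A', 'S')``) identifying the anatomical
        orientation; the axial plane is spanned by the two non-S/I axes.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if np.iscomplexobj(self.data):
            raise ValueError("magnitude volume must be real-valued")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("magnitude volume must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ComplexImage:
    """A square 2-D complex image slice.

    ``meta`` records provenance (seed, source volume/slice, processing
    stage) and is propagated, not interpreted.
    """

    data: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"image must be square 2-D, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def phase(self) -> np.ndarray:
        return np.angle(self.data)


@dataclass
class CoilSensitivities:
    """Complex coil sensitivity maps, shape ``n x n x nc``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"coil maps must be n x n x nc, got {self.data.shape}")
        if self.data.shape[2] < 1:
            raise ValueError("need at least one coil")

    @property
    def nc(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude across coils."""
        return np.sqrt(np.sum(np.abs(self.data) ** 2, axis=2))


@dataclass
class SamplingMask:
    """Binary k-space sampling mask on an ``n x n`` centered grid.

    ``info`` carries generator metadata (e.g. the Poisson-disc minimum
    distance actually used).
    """

    data: np.ndarray
    info: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError("mask must be binary")
        self.data = arr.astype(bool)
        if self.data.sum() == 0:
            raise ValueError("mask must sample at least one position")

    @property
    def n_sampled(self) -> int:
        return int(self.data.sum())

    @property
    def accel(self) -> float:
        """Achieved acceleration = grid size / number of sampled positions."""
        return self.data.size / self.n_sampled


@dataclass
class KSpace:
    """Multi-coil k-space data ``n x n x nc`` with zeros off the mask."""

    data: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"k-space must be n x n x nc, got {self.data.shape}")
        if self.data.shape[:2] != self.mask.data.shape:
            raise ValueError("k-space / mask shape mismatch")
        # enforce the invariant rather than trusting the caller
        self.data = self.data * self.mask.data[:, :, None]

    @property
    def nc(self) -> int:
        return self.data.shape[2]
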