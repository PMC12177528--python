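"""Curation pipeline turning magnitude volumes into normalized training slices.

Steps: (i) resample so the axial plane is square at the target size,
(ii) split into axial 2-D slices, (iii) add background Gaussian noise and
normalize each slice by its maximum, (iv) compute mean/std over a corner
patch, (v) exclude content-free slices whose corner statistics fall below
both thresholds.

The background-noise std is interpreted in raw pre-normalization intensity
units (the noise is added before the divide-by-max of the same step); on a
max-1 image a std of 5 would destroy the content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import MagnitudeVolume

__all__ = [
    "SliceRecord",
    "conform_resample",
    "split_axial",
    "add_background_noise",
    "normalize_slice",
    "corner_patch_stats",
    "filter_slices",
    "preprocess_volume",
]

MEAN_THRESHOLD = 0.04
STD_THRESHOLD = 0.0061
PATCH_SIZE = 30
REFERENCE_SIZE = 256  # patch size scales as PATCH_SIZE/REFERENCE_SIZE * n


@dataclass(eq=False)
class SliceRecord:
    """A candidate training slice with its corner-patch statistics."""

    image: np.ndarray
    patch_mean: float
    patch_std: float
    kept: bool
    source: tuple[str, int]


def _axial_axes(vol: MagnitudeVolume) -> tuple[int, int, int]:
    """(in-plane axis a, in-plane axis b, through-plane axis).

    The through-plane axis is the one labelled S/I (head-foot); if no such
    label exists the last axis is used.
    """
    through = 2
    for ax, code in enumerate(vol.orientation):
        if code in ("S", "I"):
            through = ax
    inplane = [ax for ax in range(3) if ax != through]
    return inplane[0], inplane[1], through


def conform_resample(vol: MagnitudeVolume, target_size: int = 256) -> MagnitudeVolume:
    """Resample the two in-plane (axial) axes to ``target_size`` each.

    Linear interpolation, which preserves non-negativity; the through-plane
    axis and its voxel size are untouched. The output is re-ordered so the
    through-plane axis is last.
    """
    a, b, through = _axial_axes(vol)
    data = np.transpose(vol.data, (a, b, through))
    na, nb = data.shape[0], data.shape[1]
    if na == 0 or nb == 0 or data.shape[2] == 0:
        raise ValueError("degenerate (zero-extent) axis")
    zoom = (target_size / na, target_size / nb, 1.0)
    if na == target_size and nb == target_size:
        out = data.astype(np.float64).copy()
    else:
        out = ndimage.zoom(data.astype(np.float64), zoom, order=1, mode="nearest")
        # guard against shape-off-by-one from rounding
        out = out[:target_size, :target_size, :]
    out = np.clip(out, 0, None)
    vs = vol.voxel_size
    new_vs = (vs[a] * na / target_size, vs[b] * nb / target_size, vs[through])
    ori = vol.orientation
    return MagnitudeVolume(out, voxel_size=new_vs,
                           orientation=(ori[a], ori[b], ori[through]))


def split_axial(vol: MagnitudeVolume) -> list[np.ndarray]:
    """Split a conformed volume into its axial 2-D slices (copies)."""
    return [vol.data[:, :, k].copy() for k in range(vol.data.shape[2])]


def add_background_noise(
    slc: np.ndarray, mu: float = 0.003, sigma: float = 5.0, seed: int = 0
) -> np.ndarray:
    """Add i.i.d. Gaussian noise N(mu, sigma^2) per pixel, clipped at zero.

    Emulates the background noise floor present in real magnitude images;
    units are the raw (pre-normalization) intensity units of the slice.
    """
    rng = np.random.default_rng(seed)
    out = slc + rng.normal(loc=mu, scale=sigma, size=slc.shape)
    return np.clip(out, 0, None)


def normalize_slice(slc: np.ndarray) -> np.ndarray:
    """Divide by the maximum pixel value so the max is exactly 1."""
    m = float(slc.max())
    if m <= 0:
        raise ValueError("cannot normalize an all-zero slice")
    return slc / m


def corner_patch_stats(slc: np.ndarray, patch_size: int | None = None) -> tuple[float, float]:
    """Mean and population std over the corner patch anchored at (0, 0).

    The nominal patch is 30x30 at the reference size of 256; for smaller
    test sizes it scales proportionally (at least 2 pixels).
    """
    n = slc.shape[0]
    if patch_size is None:
        patch_size = max(2, round(PATCH_SIZE * n / REFERENCE_SIZE))
    if n < patch_size or slc.shape[1] < patch_size:
        raise ValueError("slice smaller than the corner patch")
    patch = slc[:patch_size, :patch_size]
    return float(patch.mean()), float(patch.std())  # population convention


def filter_slices(
    records: list[SliceRecord],
    mean_threshold: float = MEAN_THRESHOLD,
    std_threshold: float = STD_THRESHOLD,
    combine: str = "and",
) -> list[SliceRecord]:
    """Mark records kept/excluded and return the kept ones, order preserved.

    A slice is excluded iff BOTH its corner mean and std are below their
    thresholds (content-free background). ``combine='or'`` switches to the
    more aggressive disjunction for sensitivity analysis.
    """
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    kept = []
    for rec in records:
        low_mu = rec.patch_mean < mean_threshold
        low_sd = rec.patch_std < std_threshold
        excluded = (low_mu and low_sd) if combine == "and" else (low_mu or low_sd)
        rec.kept = not excluded
        if rec.kept:
            kept.append(rec)
    return kept


def preprocess_volume(
    vol: MagnitudeVolume,
    volume_id: str = "vol",
    target_size: int = 256,
    noise_mu: float = 0.003,
    noise_sigma: float = 5.0,
    seed: int = 0,
    mean_threshold: float = MEAN_THRESHOLD,
    std_threshold: float = STD_THRESHOLD,
) -> list[SliceRecord]:
    """Run the full curation pipeline on one volume.

    Deterministic given (volume, seed): slice k uses the sub-seed seed + k.
    Returns all slice records (kept flag set); kept slices have max exactly 1.
    """
    conf = conform_resample(vol, target_size=target_size)
    records = []
    for k, slc in enumerate(split_axial(conf)):
        noisy = add_background_noise(slc, mu=noise_mu, sigma=noise_sigma, seed=seed + k)
        norm = normalize_slice(noisy)
        mu, sd = corner_patch_stats(norm)
        records.append(SliceRecord(norm, mu, sd, kept=True, source=(volume_id, k)))
    filter_slices(records, mean_threshold, std_threshold)
    return records


def manifest_rows(records: list[SliceRecord]) -> list[dict]:
    """CSV-ready manifest rows (source, patch stats, kept flag)."""
    return [
        {
            "volume": r.source[0],
            "slice": r.source[1],
            "patch_mean": r.patch_mean,
            "patch_std": r.patch_std,
            "kept": r.kept,
        }
        for r in records
    ]


def write_manifest(records: list[SliceRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(manifest_rows(records)).to_csv(path, index=False)
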