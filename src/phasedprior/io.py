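"""File I/O: NIfTI magnitude volumes, CFL-dialect complex arrays, run configs.

Complex arrays are stored in the CFL dialect used by common reconstruction
toolboxes: a raw little-endian 32-bit interleaved real/imag file (``.cfl``,
column-major) paired with a text header (``.hdr``) whose second line lists
the dimensions.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import MagnitudeVolume

__all__ = [
    "read_magnitude_volume",
    "write_cfl",
    "read_cfl",
    "write_config",
    "read_config",
    "stage_timer",
]

log = logging.getLogger("phasedprior")


def read_magnitude_volume(path: str | Path) -> MagnitudeVolume:
    """Load a 3-D magnitude volume from a NIfTI file.

    Voxel size and axis orientation are populated from the header. Complex
    or non-3-D data are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if np.iscomplexobj(data):
        raise ValueError(f"{path}: complex-valued NIfTI is not a magnitude volume")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got shape {data.shape}")
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    orientation = nib.aff2axcodes(img.affine)
    return MagnitudeVolume(
        data=np.ascontiguousarray(data, dtype=np.float64),
        voxel_size=voxel,
        orientation=orientation,
    )


def _base(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix in (".cfl", ".hdr"):
        p = p.with_suffix("")
    return p


def write_cfl(path: str | Path, array: np.ndarray) -> None:
    """Write a complex array as a ``.cfl``/``.hdr`` pair.

    Values are stored as interleaved float32 real/imag in column-major
    order; the header lists the dimensions padded to five axes, matching
    the layout common reconstruction toolboxes expect.
    """
    arr = np.asarray(array, dtype=np.complex64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("refusing to write non-finite array")
    base = _base(path)
    dims = list(arr.shape) + [1] * (5 - arr.ndim)
    base.with_suffix(".hdr").write_text(
        "# Dimensions\n" + " ".join(str(d) for d in dims) + "\n"
    )
    with open(base.with_suffix(".cfl"), "wb") as fh:
        arr.T.astype(np.complex64).tofile(fh)  # .T gives column-major byte order


def read_cfl(path: str | Path) -> np.ndarray:
    """Read a ``.cfl``/``.hdr`` pair; trailing singleton axes are squeezed."""
    base = _base(path)
    hdr = base.with_suffix(".hdr")
    cfl = base.with_suffix(".cfl")
    if not hdr.exists() or not cfl.exists():
        raise FileNotFoundError(f"missing {hdr} or {cfl}")
    lines = hdr.read_text().splitlines()
    dim_line = next(ln for ln in lines if not ln.startswith("#"))
    dims = [int(t) for t in dim_line.split()]
    raw = np.fromfile(cfl, dtype=np.complex64)
    expected = int(np.prod(dims))
    if raw.size != expected:
        raise ValueError(
            f"{cfl}: header declares {expected} elements, file holds {raw.size}"
        )
    arr = raw.reshape(dims[::-1]).T  # undo column-major layout
    while arr.ndim > 2 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return np.ascontiguousarray(arr)


def write_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@contextmanager
def stage_timer(name: str):
    """Log wall time of a pipeline stage at INFO level."""
    t0 = time.perf_counter()
    try:
        yield
    finally:
        log.info("stage %-20s %.3f s", name, time.perf_counter() - t0)
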