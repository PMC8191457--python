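"""NIfTI-backed volume and ROI-mask I/O with strict grid checking.

All analysis operates on axis-aligned grids in (x, y, z) voxel order with
0-based indices.  Images carry calibrated scalar values (Hounsfield units for
CT), a per-axis voxel spacing in millimetres and a physical origin.  Masks
must live on the exact grid of their companion image; a mismatch signals
mis-registered inputs and is always an error, never silently resampled.

Missing values (voxels excluded from analysis) are represented in memory as
NaN.  NIfTI has no missing-value convention, so on disk NaNs are replaced by
a sentinel recorded in a plain-text sidecar next to the file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ROIMask",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
]

#: sentinel written to disk in place of NaN missing markers
DEFAULT_SENTINEL = -32768.0

#: tolerance (mm) for spacing/origin agreement between an image and its mask
GRID_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when a mask does not share its reference image's grid."""


def _check_grid_fields(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise ValueError(f"non-3D array: expected 3 dimensions, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"empty volume shape {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be three finite positive values, got {spacing}")
    origin = np.asarray(origin, dtype=float)
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError(f"origin must be three finite values, got {origin}")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid (HU for CT) with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        _check_grid_fields(data, self.spacing, self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROIMask:
    """A binary region-of-interest on the grid of a companion image."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data) != 0
        _check_grid_fields(data, self.spacing, self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


def grids_match(a, b, tol: float = GRID_TOL_MM) -> bool:
    """True if ``a`` and ``b`` share shape, spacing and origin (within ``tol`` mm)."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


def require_same_grid(a, b, what: str = "mask") -> None:
    if not grids_match(a, b):
        raise GridMismatchError(
            f"{what} grid mismatch: shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing}, origin {a.origin} vs {b.origin}"
        )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _sidecar_path(path: str) -> str:
    return str(path) + ".sentinel.txt"


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI volume.

    Spacing is taken from the header zooms, the origin from the affine
    translation.  If a sentinel sidecar is present, sentinel voxels are
    restored to NaN (missing).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D array: {path} has ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asarray(data, dtype=float)
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            sentinel = float(fh.read().strip())
        data[data == sentinel] = np.nan
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def write_volume(vol: ImageVolume, path, sentinel: float = DEFAULT_SENTINEL) -> None:
    """Write a volume (or parametric map) as NIfTI-1.

    NaN missing markers are stored as ``sentinel`` and the sentinel value is
    recorded in a plain-text sidecar ``<path>.sentinel.txt``.  Integer-valued
    label maps round-trip exactly (stored as int32 when lossless).
    """
    data = np.asarray(vol.data, dtype=float)
    has_missing = bool(np.isnan(data).any())
    out = data.copy()
    if has_missing:
        out[np.isnan(out)] = sentinel
    finite = out[np.isfinite(out)]
    if finite.size and np.all(finite == np.round(finite)) and np.all(np.abs(finite) < 2**31):
        out = out.astype(np.int32)
    img = nib.Nifti1Image(out, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    if has_missing:
        with open(sidecar, "w") as fh:
            fh.write(f"{sentinel}\n")
    elif os.path.exists(sidecar):
        os.remove(sidecar)


def read_mask(path, reference: ImageVolume) -> ROIMask:
    """Read a binary mask and verify it lives on ``reference``'s grid."""
    vol = read_volume(path)
    mask = ROIMask(data=vol.data != 0, spacing=vol.spacing, origin=vol.origin)
    require_same_grid(reference, mask, what=f"mask {path}")
    return mask


def write_mask(mask: ROIMask, path) -> None:
    write_volume(
        ImageVolume(mask.data.astype(float), mask.spacing, mask.origin), path
    )
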