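"""Bring image and masks to the analysis grid and define analysis regions.

The analysis grid is isotropic (default 3.3 mm cubic voxels): the CT is
resampled with trilinear interpolation, masks with nearest neighbour, and
the soft-tissue Hounsfield window (default [-20, 180] HU, both ends
inclusive) is applied afterwards.  Voxels outside the ROI or outside the
window carry NaN and are treated identically everywhere downstream.

The region pair used by the bi-regional model is derived from the primary
tumor mask (GTV) and the recurrence mask: GTVrec = GTV intersect recurrence,
GTVcontrol = GTV minus recurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import ImageVolume, ROIMask, require_same_grid

__all__ = [
    "MaskedVolume",
    "resample_isotropic",
    "resample_mask_isotropic",
    "apply_hu_window",
    "remove_artifact_slices",
    "segment_relative_threshold",
    "derive_region_pair",
    "check_min_volume",
]

#: analysis defaults (all overridable through RunConfig)
TARGET_SPACING_MM = 3.3
WINDOW_LOW_HU = -20.0
WINDOW_HIGH_HU = 180.0
MIN_VOXELS = 27
PET_FRACTION = 0.4


@dataclass(frozen=True)
class MaskedVolume:
    """An image restricted to an ROI; excluded voxels carry NaN.

    ``data`` holds raw intensities (HU) for voxels inside the ROI and inside
    the intensity window, NaN elsewhere.  ``window`` is the closed intensity
    interval that was applied.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    window: tuple[float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))

    @property
    def shape(self):
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.data)

    @property
    def roi_voxel_count(self) -> int:
        return int(self.valid.sum())

    def roi_mask(self) -> ROIMask:
        """The set of analysable (non-missing) voxels as an ROIMask."""
        return ROIMask(self.valid, self.spacing, self.origin)


def _target_grid(shape, spacing, target: float):
    """Output shape for corner-aligned resampling to ``target`` mm voxels."""
    return tuple(int(math.ceil(n * s / target)) for n, s in zip(shape, spacing))


def _resample(data: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    out_shape = _target_grid(data.shape, spacing, target)
    # sample at physical positions j*target along each axis (corner-aligned,
    # origin preserved); input index = physical / input spacing
    grids = [
        np.arange(n_out) * target / s for n_out, s in zip(out_shape, spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(
        data, np.stack(coords), order=order, mode="nearest"
    )


def resample_isotropic(vol: ImageVolume, target: float = TARGET_SPACING_MM) -> ImageVolume:
    """Resample to cubic voxels of ``target`` mm using trilinear interpolation.

    The output grid is corner-aligned with the input (same origin) and covers
    the input's physical extent: output shape = ceil(n_i * s_i / target).
    """
    if not (target > 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    data = _resample(vol.data, vol.spacing, target, order=1)
    return ImageVolume(data, (target,) * 3, vol.origin)


def resample_mask_isotropic(mask: ROIMask, target: float = TARGET_SPACING_MM) -> ROIMask:
    """Nearest-neighbour companion of :func:`resample_isotropic` for masks."""
    if not (target > 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    data = _resample(mask.data.astype(np.uint8), mask.spacing, target, order=0)
    return ROIMask(data, (target,) * 3, mask.origin)


def apply_hu_window(
    vol: ImageVolume,
    roi: ROIMask,
    low: float = WINDOW_LOW_HU,
    high: float = WINDOW_HIGH_HU,
) -> MaskedVolume:
    """Restrict ``vol`` to ``roi`` and the closed intensity window [low, high].

    Voxels outside the ROI, or with intensity outside the window, become NaN.
    """
    if low >= high:
        raise ValueError(f"window low ({low}) must be below high ({high})")
    require_same_grid(vol, roi, what="ROI")
    data = np.where(roi.data & (vol.data >= low) & (vol.data <= high), vol.data, np.nan)
    return MaskedVolume(data, vol.spacing, (float(low), float(high)), vol.origin)


def remove_artifact_slices(mask: ROIMask, slice_indices) -> ROIMask:
    """Clear mask foreground on the given z-slices (metal-artifact removal).

    Slice indices are user supplied; artifact detection is out of scope.
    """
    nz = mask.shape[2]
    data = mask.data.copy()
    for z in slice_indices:
        z = int(z)
        if not (0 <= z < nz):
            raise IndexError(f"slice index {z} out of range [0, {nz})")
        data[:, :, z] = False
    return ROIMask(data, mask.spacing, mask.origin)


def segment_relative_threshold(vol: ImageVolume, fraction: float = PET_FRACTION) -> ROIMask:
    """Threshold at ``fraction`` of the volume maximum (e.g. 40% of SUVmax).

    Returns the mask of voxels with value >= fraction * max.  Works on any
    positive-valued scalar volume (SUV or raw activity).
    """
    vmax = float(np.nanmax(vol.data))
    if not (vmax > 0):
        raise ValueError(f"volume maximum must be positive, got {vmax}")
    mask = vol.data >= fraction * vmax
    return ROIMask(mask, vol.spacing, vol.origin)


def derive_region_pair(gtv: ROIMask, rec: ROIMask) -> tuple[ROIMask, ROIMask]:
    """Split the GTV into (GTVrec, GTVcontrol) by the recurrence mask.

    GTVrec = GTV intersect recurrence; GTVcontrol = GTV minus recurrence.
    The pair is disjoint and its union is the GTV.
    """
    require_same_grid(gtv, rec, what="recurrence mask")
    gtvrec = ROIMask(gtv.data & rec.data, gtv.spacing, gtv.origin)
    gtvcontrol = ROIMask(gtv.data & ~rec.data, gtv.spacing, gtv.origin)
    return gtvrec, gtvcontrol


def check_min_volume(region, minimum: int = MIN_VOXELS) -> bool:
    """True iff the region has at least ``minimum`` analysable voxels."""
    if isinstance(region, MaskedVolume):
        count = region.roi_voxel_count
    elif isinstance(region, ROIMask):
        count = region.voxel_count
    else:
        count = int(np.sum(~np.isnan(np.asarray(region, dtype=float))))
    return count >= minimum
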