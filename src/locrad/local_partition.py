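"""Divide a tumor mask into disjoint sub-regions and label them.

Two schemes are provided:

* ``fixed_count`` — three axis-aligned cutting planes through the (rounded)
  center of mass of the GTV split the ROI into 8 octants; the octants scale
  with tumor size, so every patient contributes the same number of
  sub-regions.
* ``fixed_size`` — a non-overlapping g^3 voxel grid (default 5x5x5) tiles
  the GTV bounding box; the grid's global offset is searched exhaustively
  over shift^3 candidates and chosen to maximise the number of cells with at
  least T ROI voxels (default T = 25), i.e. to cover as much of the tumor as
  possible.  Cell sizes are constant; the number of cells varies per tumor.

Sub-regions are pairwise disjoint in both schemes — sub-region descriptors
stay independent of one another.  Each sub-region is labelled from the
recurrence overlap: recurrent iff strictly more than half of its ROI voxels
lie inside GTVrec, otherwise control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging_io import ImageVolume, ROIMask, require_same_grid
from .preprocessing import MIN_VOXELS, MaskedVolume
from .texture_features import (
    DEFAULT_BIN_WIDTH,
    FEATURE_NAMES,
    SmallRegionError,
    extract_feature_vector,
)

__all__ = [
    "SubRegion",
    "Partition",
    "gtv_center",
    "partition_fixed_count",
    "partition_fixed_size",
    "label_subregions",
    "build_feature_table",
    "export_parametric_map",
]

logger = logging.getLogger(__name__)

FIXED_COUNT_K = 8
GRID_SIZE = 5
GRID_SHIFT = 5
GRID_MIN_VOXELS = 25
LABEL_THRESHOLD = 0.5  # strict: recurrent iff overlap fraction > threshold


@dataclass(frozen=True)
class SubRegion:
    """One sub-region of a partition: its ROI voxels and recurrence label."""

    id: int
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]  # ROI voxel coordinates
    label: str = "unlabeled"  # control | recurrent | unlabeled
    overlap_fraction: float = 0.0

    @property
    def roi_voxel_count(self) -> int:
        return int(self.indices[0].size)


@dataclass(frozen=True)
class Partition:
    """A set of disjoint sub-regions of one GTV mask."""

    scheme: str  # fixed_count | fixed_size
    shape: tuple[int, int, int]
    subregions: tuple[SubRegion, ...]
    params: dict = field(default_factory=dict)

    @property
    def retained(self) -> tuple[SubRegion, ...]:
        """Sub-regions that actually contain ROI voxels."""
        return tuple(s for s in self.subregions if s.roi_voxel_count > 0)


def gtv_center(mask: ROIMask) -> tuple[int, int, int]:
    """Rounded (half-up) center of mass of the mask foreground, in voxels."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask has no center")
    com = [float(c.mean()) for c in np.nonzero(mask.data)]
    return tuple(int(np.floor(c + 0.5)) for c in com)


def partition_fixed_count(mask: ROIMask, k: int = FIXED_COUNT_K) -> Partition:
    """Split the ROI into 8 octants about the GTV center.

    The three cutting planes pass through :func:`gtv_center`; a voxel whose
    index equals the center coordinate on an axis goes to the upper half.
    Empty octants are kept (flagged by a zero voxel count) so every patient
    has exactly 8 sub-regions; they are excluded from feature extraction.
    """
    if k != 8:
        raise ValueError("the fixed-count scheme is defined for k = 8 octants")
    center = gtv_center(mask)
    xs, ys, zs = np.nonzero(mask.data)
    octant = (
        (xs >= center[0]).astype(int)
        + 2 * (ys >= center[1]).astype(int)
        + 4 * (zs >= center[2]).astype(int)
    )
    subregions = []
    for i in range(8):
        sel = octant == i
        subregions.append(SubRegion(id=i, indices=(xs[sel], ys[sel], zs[sel])))
    return Partition(
        scheme="fixed_count",
        shape=mask.shape,
        subregions=tuple(subregions),
        params={"k": 8, "center": center},
    )


def _cell_counts(xs, ys, zs, start, g):
    """Cell index per ROI voxel and per-cell voxel counts for one offset."""
    cx = (xs - start[0]) // g
    cy = (ys - start[1]) // g
    cz = (zs - start[2]) // g
    ncx, ncy, ncz = int(cx.max()) + 1, int(cy.max()) + 1, int(cz.max()) + 1
    flat = (cx * ncy + cy) * ncz + cz
    counts = np.bincount(flat, minlength=ncx * ncy * ncz)
    return flat, counts


def partition_fixed_size(
    mask: ROIMask,
    g: int = GRID_SIZE,
    shift: int = GRID_SHIFT,
    min_cell_voxels: int = GRID_MIN_VOXELS,
) -> Partition:
    """Tile the GTV with a g^3 grid, optimally placed, keeping cells >= T.

    All shift^3 global offsets are scored exhaustively; the offset covering
    the largest analysed tumor volume (total ROI voxels inside retained
    cells) wins, ties broken by the lexicographically smallest offset.
    """
    if mask.voxel_count == 0:
        raise ValueError("empty mask cannot be partitioned")
    xs, ys, zs = np.nonzero(mask.data)
    bb_min = np.array([xs.min(), ys.min(), zs.min()])
    best = None  # (covered, neg_offset) to maximise
    for off in itertools.product(range(shift), repeat=3):
        start = bb_min - np.array(off)
        flat, counts = _cell_counts(xs, ys, zs, start, g)
        retained = counts >= min_cell_voxels
        covered = int(counts[retained].sum())
        key = (covered, tuple(-o for o in off))
        if best is None or key > best[0]:
            best = (key, off, start, flat, counts, retained)
    key, off, start, flat, counts, retained = best
    if key[0] == 0:
        raise ValueError(
            f"no {g}x{g}x{g} cell reaches {min_cell_voxels} ROI voxels at any "
            f"offset: tumor not analysable with the fixed-size scheme"
        )
    subregions = []
    for sid, cell in enumerate(np.flatnonzero(retained)):
        sel = flat == cell
        subregions.append(SubRegion(id=sid, indices=(xs[sel], ys[sel], zs[sel])))
    return Partition(
        scheme="fixed_size",
        shape=mask.shape,
        subregions=tuple(subregions),
        params={
            "g": g,
            "shift": shift,
            "min_cell_voxels": min_cell_voxels,
            "offset": tuple(int(o) for o in off),
            "n_candidates": shift**3,
        },
    )


def label_subregions(
    partition: Partition,
    gtvrec: ROIMask,
    threshold: float = LABEL_THRESHOLD,
) -> Partition:
    """Label each sub-region from its overlap with the recurrence region.

    ``recurrent`` iff strictly more than ``threshold`` of the sub-region's
    ROI voxels lie inside GTVrec; otherwise ``control``.  The denominator is
    the sub-region's ROI voxel count (only ROI voxels are ever analysed).
    """
    if partition.shape != gtvrec.shape:
        raise ValueError(
            f"grid mismatch: partition shape {partition.shape} vs mask {gtvrec.shape}"
        )
    labelled = []
    for sub in partition.subregions:
        n = sub.roi_voxel_count
        if n == 0:
            labelled.append(replace(sub, label="unlabeled", overlap_fraction=0.0))
            continue
        frac = float(gtvrec.data[sub.indices].sum()) / n
        label = "recurrent" if frac > threshold else "control"
        labelled.append(replace(sub, label=label, overlap_fraction=frac))
    return replace(partition, subregions=tuple(labelled))


def subregion_masked_volume(volume: MaskedVolume, sub: SubRegion) -> MaskedVolume:
    """Restrict ``volume`` to one sub-region (all other voxels missing)."""
    data = np.full(volume.shape, np.nan)
    data[sub.indices] = volume.data[sub.indices]
    return MaskedVolume(data, volume.spacing, volume.window, volume.origin)


def build_feature_table(
    volume: MaskedVolume,
    partition: Partition,
    patient_id: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_voxels: int | None = None,
) -> pd.DataFrame:
    """One row of 161 features per retained sub-region.

    The minimum analysable-voxel count defaults to 27 for the fixed-count
    scheme (whose octants scale with the tumor) and to the grid's own
    retention threshold for the fixed-size scheme.  Sub-regions below the
    minimum are dropped with a logged reason, never silently.
    """
    if min_voxels is None:
        min_voxels = (
            partition.params.get("min_cell_voxels", GRID_MIN_VOXELS)
            if partition.scheme == "fixed_size"
            else MIN_VOXELS
        )
    rows = []
    for sub in partition.retained:
        sub_mv = subregion_masked_volume(volume, sub)
        try:
            feats = extract_feature_vector(sub_mv, bin_width, min_voxels=min_voxels)
        except SmallRegionError as exc:
            logger.info(
                "patient %s: sub-region %d dropped (%s)", patient_id, sub.id, exc
            )
            continue
        row = {
            "patient_id": patient_id,
            "region_id": sub.id,
            "label": sub.label,
            "roi_voxel_count": sub_mv.roi_voxel_count,
            "overlap_fraction": sub.overlap_fraction,
        }
        row.update(feats)
        rows.append(row)
    meta = ["patient_id", "region_id", "label", "roi_voxel_count", "overlap_fraction"]
    return pd.DataFrame(rows, columns=meta + list(FEATURE_NAMES))


def export_parametric_map(
    partition: Partition,
    values,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageVolume:
    """Paint one scalar per retained sub-region over its ROI voxels.

    Produces the local-radiomics parametric map: every ROI voxel carries its
    sub-region's value, voxels outside any retained sub-region are missing.
    """
    values = np.asarray(values, dtype=float)
    retained = partition.retained
    if values.shape != (len(retained),):
        raise ValueError(
            f"need one value per retained sub-region: {len(retained)} regions, "
            f"{values.size} values"
        )
    data = np.full(partition.shape, np.nan)
    for sub, val in zip(retained, values):
        data[sub.indices] = val
    return ImageVolume(data, spacing, origin)
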