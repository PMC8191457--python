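"""Run configuration: every analysis constant in one validated place.

All constants default to the study settings (3.3 mm cubic grid, [-20, 180]
HU window, 27-voxel region minimum, 8 octants or a 5x5x5 grid with 5-voxel
shift and T = 25, strict >50% recurrence labelling, |r| <= 0.5 voxel-count
filter, p < 0.05 representatives, 2000 bootstrap replicates, 75th-percentile
cut-off).  Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class RunConfig:
    target_spacing: float = 3.3  # mm, cubic analysis voxels
    window_low: float = -20.0  # HU
    window_high: float = 180.0  # HU
    min_voxels: int = 27  # region minimum for feature extraction
    bin_width: float = 5.0  # HU per gray level
    pet_fraction: float = 0.4  # relative threshold for recurrence segmentation
    scheme_k: int = 8  # fixed-count sub-regions
    grid_size: int = 5  # fixed-size cell edge, voxels
    grid_shift: int = 5  # offset search range per axis
    grid_min_voxels: int = 25  # T, fixed-size retention threshold
    label_threshold: float = 0.5  # strict: recurrent iff fraction > threshold
    r_max: float = 0.5  # voxel-count correlation filter
    p_max: float = 0.05  # representative Wald p gate
    bootstrap_replicates: int = 2000
    cutoff_percentile: float = 75.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
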