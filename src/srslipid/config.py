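"""Pipeline configuration: one YAML file with full defaults.

Every tunable of every stage lives here so that unreported-parameter choices
are visible and versionable; unknown keys are rejected rather than ignored.
CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .cell_segmentation import CellSegmentationParams
from .io_stacks import VoxelGeometry
from .ld_segmentation import SegmentationParams
from .phantom import PhantomSpec
from .preprocess import PreprocessParams

__all__ = ["StatsOptions", "UnsaturationOptions", "PipelineConfig"]


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    bin_width: float = 5.0  # μm³ size-bin width
    confidence: float = 0.95
    welch: bool = False


@dataclass(frozen=True)
class UnsaturationOptions:
    # "auto" = floor_sigmas × robust background σ of the baseline-subtracted
    # 2900 stack; with intensity-weighted droplet ratios the floor only
    # guards against near-zero denominators (a tight floor preferentially
    # admits positive noise excursions at depth and biases the ratio down)
    denominator_floor: float | str = "auto"
    floor_sigmas: float = 3.0
    # light in-plane smoothing of the ratio channels: a bias-variance
    # compromise set to ~1/4 of the typical droplet radius (heavier blur
    # mixes cytoplasm into droplet boundary voxels; none leaves the
    # per-droplet ratio noise-limited); kept 2D to avoid the anisotropic
    # axial mixing of 1 μm z-steps
    smooth_sigma_xy: float = 0.3
    smooth_sigma_z: float = 0.0
    # per-droplet ratio estimator: "background_corrected" subtracts the local
    # cytoplasm pedestal from both channel sums, cancelling partial-volume
    # and smoothing mixing; "summed" is plain ΣI3010/ΣI2900; "voxel_mean"
    # averages per-voxel ratios
    mode: str = "background_corrected"


def _build(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {name} config key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the run seed."""

    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(0.3, 0.3, 1.0))
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    unsaturation: UnsaturationOptions = field(default_factory=UnsaturationOptions)
    cell: CellSegmentationParams = field(default_factory=CellSegmentationParams)
    stats: StatsOptions = field(default_factory=StatsOptions)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    restrict_to_cell: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        sections = {
            "geometry": VoxelGeometry,
            "preprocess": PreprocessParams,
            "segmentation": SegmentationParams,
            "unsaturation": UnsaturationOptions,
            "cell": CellSegmentationParams,
            "stats": StatsOptions,
        }
        for key, section_cls in sections.items():
            if key in data:
                kwargs[key] = _build(section_cls, data.pop(key), key)
        if "phantom" in data:
            ph = dict(data.pop("phantom"))
            if "geometry" in ph:
                ph["geometry"] = _build(VoxelGeometry, ph["geometry"], "phantom.geometry")
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "cells" in ph:
                ph["cells"] = tuple((tuple(c), float(r)) for c, r in ph["cells"])
            if ph.get("attenuation_length") in ("inf", ".inf"):
                ph["attenuation_length"] = np.inf
            kwargs["phantom"] = _build(PhantomSpec, ph, "phantom")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        if np.isinf(d["phantom"]["attenuation_length"]):
            d["phantom"]["attenuation_length"] = "inf"
        d["phantom"]["cells"] = [
            [list(center), radius] for center, radius in d["phantom"]["cells"]
        ]
        d["phantom"]["grid_shape"] = list(d["phantom"]["grid_shape"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
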