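"""Stage composition: the full image-processing workflow.

Order of operations per run: per-plane baseline subtraction → Gaussian
smoothing (both channels) → Bradley per-plane droplet masks on the 2900
channel → restriction to the segmented cell body (droplets are
intracellular; this also discards out-of-sample noise blobs) → 3D
connected-component labeling and size filtering → per-droplet half-maximum
boundary refinement → geometry measurement → per-voxel 3010/2900 ratio map
and per-droplet unsaturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cell_segmentation import (
    CellLabelVolume,
    NoCellFoundError,
    assign_droplets_to_cells,
    segment_cell_mask,
    split_two_cells,
)
from .config import PipelineConfig
from .io_stacks import LipidDroplet, RamanChannelStack
from .ld_segmentation import (
    label_components_3d,
    measure_lds,
    refine_labels_half_max,
    segment_lds,
)
from .preprocess import gaussian_smooth, subtract_baseline
from .unsaturation import (
    RatioMap,
    attach_unsaturation,
    compute_ratio_map,
    estimate_background_sigma,
)

logger = logging.getLogger("srslipid")

__all__ = ["PipelineResult", "preprocess_stack", "run_ld_pipeline", "run_two_cell_pipeline"]


@dataclass
class PipelineResult:
    """Everything the droplet pipeline produces for one embryo stack pair."""

    droplets: list[LipidDroplet]
    ld_labels: np.ndarray
    ratio_map: RatioMap
    cell_mask: np.ndarray | None
    pre2900: RamanChannelStack
    pre3010: RamanChannelStack
    denominator_floor: float


def preprocess_stack(stack: RamanChannelStack, config: PipelineConfig) -> RamanChannelStack:
    """Baseline subtraction (unclipped) followed by Gaussian smoothing.

    The pipeline keeps signed residual noise through smoothing: clipping
    before smoothing rectifies zero-mean noise into a positive pedestal that
    biases the weak-channel numerator of the unsaturation ratio.  Thresholds
    downstream are strictly positive, so signed background noise never
    reaches a mask, and the ratio map enforces nonnegativity itself.
    """
    import dataclasses

    params = dataclasses.replace(config.preprocess, clip_negative=False)
    return gaussian_smooth(subtract_baseline(stack, params), params)


_MIN_BG_PIXELS = 500


def _refine_baseline(
    subtracted: np.ndarray, bg_planes: np.ndarray
) -> np.ndarray:
    """Second-pass per-plane baseline residual from acellular pixels.

    The coarse percentile baseline assumes its anchors fall on background,
    which drifts with the cell's fill fraction; once the cell body is known,
    the median over out-of-cell pixels estimates each plane's residual
    offset without any distributional assumption.  Planes with too few
    background pixels keep the coarse estimate.
    """
    out = subtracted.copy()
    for z in range(subtracted.shape[0]):
        sel = bg_planes[z]
        if int(sel.sum()) >= _MIN_BG_PIXELS:
            out[z] -= float(np.median(subtracted[z][sel]))
    return out


def _resolve_floor(config: PipelineConfig, ratio2900: RamanChannelStack) -> float:
    floor = config.unsaturation.denominator_floor
    if floor == "auto":
        return config.unsaturation.floor_sigmas * estimate_background_sigma(ratio2900)
    return float(floor)


def run_ld_pipeline(
    stack2900: RamanChannelStack,
    stack3010: RamanChannelStack,
    config: PipelineConfig,
) -> PipelineResult:
    """Full droplet pipeline on a co-registered 2900/3010 stack pair."""
    if stack2900.shape != stack3010.shape:
        raise ValueError(
            f"channel shape mismatch: {stack2900.shape} vs {stack3010.shape}"
        )
    import dataclasses

    from scipy import ndimage as _ndi

    coarse = dataclasses.replace(config.preprocess, clip_negative=False)
    sub2900 = subtract_baseline(stack2900, coarse)
    sub3010 = subtract_baseline(stack3010, coarse)
    pre2900 = gaussian_smooth(sub2900, coarse)
    logger.info("preprocessed stacks, shape %s", pre2900.shape)

    cell_mask = None
    restriction = None
    if config.restrict_to_cell:
        try:
            cell_mask = segment_cell_mask(pre2900, config.cell)
        except NoCellFoundError:
            logger.warning("cell segmentation found no cell; droplet mask unrestricted")

    if cell_mask is not None:
        logger.info("cell body: %d voxels", int(cell_mask.sum()))
        # second-pass baseline from acellular pixels (clear of the smoothed
        # cell boundary by a few px)
        bg = ~_ndi.binary_dilation(cell_mask, structure=np.ones((3, 9, 9), dtype=bool))
        sub2900 = sub2900.with_intensities(_refine_baseline(sub2900.intensities, bg))
        sub3010 = sub3010.with_intensities(_refine_baseline(sub3010.intensities, bg))
        pre2900 = gaussian_smooth(sub2900, coarse)
        # Erode the restriction by 1 plane / 2 px so tangential slices of
        # the cell surface (partial-volume domes at the z-extremes) cannot
        # appear as bright blobs; half-max refinement reclaims any droplet
        # edge voxels this trims.
        restriction = _ndi.binary_erosion(
            cell_mask, structure=np.ones((3, 5, 5), dtype=bool)
        )
    pre3010 = gaussian_smooth(sub3010, coarse)

    binary = segment_lds(pre2900, config.segmentation, mask=restriction)
    logger.info("Bradley segmentation: %d foreground voxels", int(binary.sum()))

    labels, count = label_components_3d(binary, config.segmentation.connectivity)
    logger.info("labeled %d droplet aggregates", count)

    # The ratio (and the refinement threshold) use lightly smoothed
    # baseline-subtracted channels, independent of the heavier detection
    # smoothing: detection blur suppresses droplet amplitudes (dilating a
    # half-maximum boundary) and mixes cytoplasm into boundary voxels.
    ratio_pp = dataclasses.replace(
        config.preprocess,
        sigma_xy=config.unsaturation.smooth_sigma_xy,
        sigma_z=config.unsaturation.smooth_sigma_z,
    )
    rat2900 = gaussian_smooth(sub2900, ratio_pp)
    rat3010 = gaussian_smooth(sub3010, ratio_pp)

    if config.segmentation.refine == "half_max" and count:
        labels = refine_labels_half_max(
            labels,
            rat2900.intensities,
            config.segmentation.connectivity,
            min_voxels=config.segmentation.min_voxels,
        )
        logger.info("half-max refinement done")

    droplets = measure_lds(labels, stack2900.geometry)
    floor = _resolve_floor(config, rat2900)
    ratio = compute_ratio_map(rat3010, rat2900, floor)
    droplets = attach_unsaturation(
        droplets,
        labels,
        ratio,
        mode=config.unsaturation.mode,
        numerator=rat3010.intensities,
        denominator=rat2900.intensities,
        profile_sigma=(
            config.unsaturation.smooth_sigma_z / stack2900.geometry.dz + 0.5,
            config.unsaturation.smooth_sigma_xy / stack2900.geometry.dy + 0.5,
            config.unsaturation.smooth_sigma_xy / stack2900.geometry.dx + 0.5,
        ),
    )
    logger.info(
        "measured %d droplets (%d with unsaturation)",
        len(droplets),
        sum(d.measured for d in droplets),
    )
    return PipelineResult(
        droplets=droplets,
        ld_labels=labels,
        ratio_map=ratio,
        cell_mask=cell_mask,
        pre2900=pre2900,
        pre3010=pre3010,
        denominator_floor=floor,
    )


def run_two_cell_pipeline(
    stack2900: RamanChannelStack,
    config: PipelineConfig,
    droplets: list[LipidDroplet] | None = None,
) -> tuple[CellLabelVolume, list[LipidDroplet] | None]:
    """Cell-morphology segmentation plus two-cell split (and LD assignment)."""
    pre2900 = preprocess_stack(stack2900, config)
    mask = segment_cell_mask(pre2900, config.cell)
    cells = split_two_cells(mask, stack2900.geometry, config.cell)
    logger.info(
        "two-cell split: volumes %s μm³",
        {k: round(v, 1) for k, v in cells.cell_volumes.items()},
    )
    assigned = assign_droplets_to_cells(droplets, cells) if droplets is not None else None
    return cells, assigned
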