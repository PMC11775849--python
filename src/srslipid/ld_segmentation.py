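"""Lipid-droplet detection in the 2900 cm⁻¹ channel.

Droplets appear as compact bright objects against dimmer cytoplasm because
their C–H chain concentration is far higher.  Detection runs a Bradley
adaptive threshold on every 2D plane (robust to depth attenuation and uneven
illumination, both of which vary slowly compared to a droplet), stacks the
masks, and labels 3D connected components.  One labeled component is the
operational "LD aggregate": droplets that touch in 3D are measured as one
object, mirroring how aggregation is quantified; no declumping is attempted.

Because droplets are sparse, the local window mean sits only slightly above
the cytoplasm level, so the adaptive threshold lands well below a droplet's
half-maximum and would dilate every blurred or partial-volume boundary.  The
optional (default) half-maximum refinement re-thresholds each detected
component at local background + half its peak height, the standard unbiased
boundary rule for blob volumetry; detection and counting happen before
refinement, so refinement changes droplet extents, never the droplet count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_stacks import LipidDroplet, RamanChannelStack, VoxelGeometry

__all__ = [
    "SegmentationParams",
    "bradley_threshold_2d",
    "segment_lds",
    "label_components_3d",
    "refine_labels_half_max",
    "measure_lds",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Droplet segmentation configuration.

    window_halfwidth
        Bradley window half-width in pixels; the local mean is taken over the
        (2w+1)² window, truncated at plane borders.  ``None`` defaults to
        1/8 of the plane width at call time.
    sensitivity
        Fraction in [0, 1): a pixel is foreground iff its value exceeds
        local_mean × (1 + sensitivity).  The margin above the local mean is
        what rejects flat cytoplasm; the default 0.6 keeps the margin several
        noise standard deviations wide for cytoplasm at the deepest
        (most attenuated) planes while staying far below the droplet peaks.
    min_voxels
        3D components smaller than this are discarded as noise.
    connectivity
        6 (faces) or 26 (faces+edges+corners) neighbourhood for 3D labeling.
    refine
        "half_max" (default) or "none" — per-droplet boundary refinement.
    """

    window_halfwidth: int | None = None
    sensitivity: float = 0.6
    min_voxels: int = 4
    connectivity: int = 26
    refine: str = "half_max"

    def __post_init__(self) -> None:
        if self.window_halfwidth is not None and self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")
        if not 0.0 <= self.sensitivity < 1.0:
            raise ValueError("sensitivity must lie in [0, 1)")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.refine not in ("half_max", "none"):
            raise ValueError("refine must be 'half_max' or 'none'")

    def resolved_halfwidth(self, plane_width: int) -> int:
        if self.window_halfwidth is not None:
            return self.window_halfwidth
        return max(1, plane_width // 8)


def _box_sum(img: np.ndarray, w: int) -> np.ndarray:
    """Sum of ``img`` over the (2w+1)² window around each pixel, truncated
    at the borders, via an integral image."""
    ny, nx = img.shape
    ii = np.zeros((ny + 1, nx + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    y = np.arange(ny)
    x = np.arange(nx)
    y0 = np.clip(y - w, 0, ny)
    y1 = np.clip(y + w + 1, 0, ny)
    x0 = np.clip(x - w, 0, nx)
    x1 = np.clip(x + w + 1, 0, nx)
    return (
        ii[np.ix_(y1, x1)]
        - ii[np.ix_(y0, x1)]
        - ii[np.ix_(y1, x0)]
        + ii[np.ix_(y0, x0)]
    )


def bradley_threshold_2d(
    plane: np.ndarray,
    params: SegmentationParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Adaptive (Bradley) threshold of one plane; returns a boolean mask.

    Foreground iff value > local_mean × (1 + sensitivity), with the local
    mean over the truncated (2w+1)² window.  Implemented with an integral
    image; equivalent to the naive sliding-window rule.

    With ``mask`` (e.g. the cell body), pixels outside it are background and
    the local mean is taken over in-mask window pixels only.  Without the
    restriction, windows straddling the sample edge are diluted by the dark
    exterior, which pulls the threshold below the flat interior level and
    floods the boundary shell foreground.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("bradley_threshold_2d expects a 2D plane")
    w = params.resolved_halfwidth(plane.shape[1])
    if mask is None:
        sums = _box_sum(plane, w)
        y = np.arange(plane.shape[0])
        x = np.arange(plane.shape[1])
        counts = np.outer(
            np.clip(y + w + 1, 0, plane.shape[0]) - np.clip(y - w, 0, plane.shape[0]),
            np.clip(x + w + 1, 0, plane.shape[1]) - np.clip(x - w, 0, plane.shape[1]),
        ).astype(np.float64)
        # value > (sum/count)·(1+s), rearranged to avoid the division
        return plane * counts > sums * (1.0 + params.sensitivity)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != plane.shape:
        raise ValueError("mask must match the plane shape")
    sums = _box_sum(np.where(mask, plane, 0.0), w)
    counts = _box_sum(mask.astype(np.float64), w)
    return mask & (plane * counts > sums * (1.0 + params.sensitivity))


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components_3d(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label maximal connected foreground components of a 3D binary volume.

    Labels are 1..count in raster-scan order of each component's first voxel;
    background stays 0.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise ValueError("expected a 3D binary volume")
    labels, count = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    return labels, int(count)


def _remove_small(binary: np.ndarray, min_voxels: int, connectivity: int) -> np.ndarray:
    labels, count = label_components_3d(binary, connectivity)
    if count == 0 or min_voxels <= 1:
        return binary
    sizes = np.bincount(labels.ravel(), minlength=count + 1)
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def segment_lds(
    stack2900: RamanChannelStack,
    params: SegmentationParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-plane Bradley masks stacked into a 3D binary volume.

    The stack must already be baseline-subtracted and smoothed.  ``mask``
    (3D, e.g. the segmented cell body) restricts each plane's threshold to
    in-mask pixels.  Components smaller than ``min_voxels`` (after 3D
    labeling) are removed.
    """
    vol = stack2900.intensities
    if vol.size == 0:
        raise ValueError("empty stack")
    binary = np.empty(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        binary[z] = bradley_threshold_2d(
            vol[z], params, mask=None if mask is None else mask[z]
        )
    return _remove_small(binary, params.min_voxels, params.connectivity)


def refine_labels_half_max(
    labels: np.ndarray,
    intensities: np.ndarray,
    connectivity: int = 26,
    pad: tuple[int, int, int] = (2, 4, 4),
    min_voxels: int = 1,
) -> np.ndarray:
    """Re-threshold each labeled component at its half-maximum boundary.

    For every component the local background is the median intensity over
    the unlabeled voxels of its padded bounding box.  The half-maximum is
    applied separably to respect the anisotropic axial blur: a z-plane of
    the box belongs to the droplet if its peak reaches background + 0.5 ×
    (global peak − background), and within each such plane voxels above
    background + 0.5 × (plane peak − background) are kept — so the lateral
    boundary of an off-centre plane is measured against that plane's own
    (axially attenuated) amplitude rather than the droplet's centre value.
    Only voxels 26/6-connected to the original component are claimed, never
    voxels of other components.  If a component's refined support separates
    into several disjoint pieces of at least ``min_voxels`` each — two
    droplets whose sub-half-maximum skirts were bridged by the dilated
    detection mask — the pieces become separate labels; such objects are
    resolvable at half-maximum and are not one aggregate.
    """
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    structure = _STRUCTURES[connectivity]
    slices = ndimage.find_objects(labels)
    next_label = int(labels.max()) + 1
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        padded = tuple(
            slice(max(s.start - p, 0), min(s.stop + p, n))
            for s, p, n in zip(sl, pad, labels.shape)
        )
        box_int = intensities[padded]
        box_lab = labels[padded]
        mine = box_lab == idx
        free = box_lab == 0
        usable = free | mine
        bg = float(np.median(box_int[free])) if free.any() else 0.0
        # peaks from a 3×3 in-plane local mean: a raw maximum over many
        # noisy voxels carries an extreme-value bias that would lift every
        # half-maximum threshold and erode the boundary
        box_sm = ndimage.uniform_filter(box_int, size=(1, 3, 3), mode="nearest")

        # stage 1: lateral half-maximum per plane (no axial gate yet)
        candidate = np.zeros_like(mine)
        for zi in range(box_int.shape[0]):
            plane_vals = np.where(usable[zi], box_sm[zi], -np.inf)
            plane_peak = float(plane_vals.max())
            if not np.isfinite(plane_peak) or plane_peak <= bg:
                continue
            thr = bg + 0.5 * (plane_peak - bg)
            candidate[zi] = usable[zi] & (box_int[zi] > thr)
        cand_labels, _ = ndimage.label(candidate, structure=structure)
        hit = np.unique(cand_labels[mine])
        hit = hit[hit > 0]
        region = out[padded]
        if hit.size == 0:
            region[mine & (region == 0)] = idx
            continue

        # stage 2: per piece, strip planes whose peak is below half the
        # piece's own peak (axial half-maximum; removes pole blur leakage)
        final = np.zeros_like(mine)
        for h in hit:
            piece = cand_labels == h
            p_peak = float(box_sm[piece].max())
            gate = bg + 0.5 * (p_peak - bg)
            keep_plane = np.array(
                [
                    piece[zi].any() and float(box_sm[zi][piece[zi]].max()) >= gate
                    for zi in range(piece.shape[0])
                ]
            )
            final |= piece & keep_plane[:, None, None]
        if not final.any():
            region[mine & (region == 0)] = idx
            continue

        # stage 3: stripping gate planes may disconnect bridged droplets —
        # relabel; the largest part keeps the label, other parts of at
        # least min_voxels become droplets of their own, fragments rejoin
        # the main part's label
        fin_labels, fin_count = ndimage.label(final, structure=structure)
        sizes = np.bincount(fin_labels.ravel(), minlength=fin_count + 1)
        sizes[0] = 0
        order = sorted(range(1, fin_count + 1), key=lambda h: (-sizes[h], h))
        main = order[0]
        region[(fin_labels == main) & (region == 0)] = idx
        for h in order[1:]:
            part = fin_labels == h
            if sizes[h] >= max(min_voxels, 1):
                region[part & (region == 0)] = next_label
                next_label += 1
            else:
                region[part & (region == 0)] = idx
    return out


def measure_lds(labels: np.ndarray, geometry: VoxelGeometry) -> list[LipidDroplet]:
    """Measure voxel count, physical volume, and centroid of every label.

    Centroids are intensity-unweighted means of voxel grid indices converted
    to physical μm and reported as (x, y, z).
    """
    labels = np.asarray(labels)
    count = int(labels.max())
    if count == 0:
        return []
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=count + 1)
    zz, yy, xx = np.indices(labels.shape).reshape(3, -1)
    sum_z = np.bincount(flat, weights=zz, minlength=count + 1)
    sum_y = np.bincount(flat, weights=yy, minlength=count + 1)
    sum_x = np.bincount(flat, weights=xx, minlength=count + 1)
    droplets = []
    for lab in range(1, count + 1):
        n = int(sizes[lab])
        if n == 0:
            continue
        droplets.append(
            LipidDroplet(
                label=lab,
                voxel_count=n,
                volume=n * geometry.voxel_volume,
                centroid=(
                    sum_x[lab] / n * geometry.dx,
                    sum_y[lab] / n * geometry.dy,
                    sum_z[lab] / n * geometry.dz,
                ),
            )
        )
    return droplets
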