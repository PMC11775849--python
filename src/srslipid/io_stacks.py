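"""Volumetric stack containers and file I/O.

Image volumes are held as ``(z, y, x)`` double-precision arrays tagged with
their Raman shift and voxel geometry.  Geometry is always caller-supplied
configuration — it is never inferred from file contents.  Coordinates reported
to users (droplet centroids, cell centres) are physical micrometres in
``(x, y, z)`` order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelGeometry",
    "RamanChannelStack",
    "HyperStack",
    "LipidDroplet",
    "StackReadError",
    "InconsistentPageShapeError",
    "NonGrayscalePageError",
    "read_stack",
    "write_stack",
    "write_droplet_table",
    "read_droplet_table",
]

DROPLET_TABLE_COLUMNS = [
    "label",
    "voxel_count",
    "volume_um3",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "mean_unsaturation",
    "cell_id",
]


class StackReadError(IOError):
    """A TIFF stack could not be read."""


class InconsistentPageShapeError(StackReadError):
    """The pages of a multi-page TIFF differ in size."""


class NonGrayscalePageError(StackReadError):
    """A TIFF page is not single-channel grayscale."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size in micrometres: ``dx``, ``dy`` per pixel, ``dz`` per plane."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel dimensions must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz


@dataclass
class RamanChannelStack:
    """A 3D intensity volume at one Raman shift.

    ``intensities`` is indexed ``(z, y, x)`` and stored as float64.
    """

    intensities: np.ndarray
    wavenumber: float
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={arr.ndim}")
        if min(arr.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def with_intensities(self, intensities: np.ndarray) -> "RamanChannelStack":
        """Copy carrying new voxel data but the same shift and geometry."""
        return RamanChannelStack(intensities, self.wavenumber, self.geometry)


@dataclass
class HyperStack:
    """An ordered series of co-registered single-shift stacks (a spectrum per voxel)."""

    frames: list[RamanChannelStack]
    wavenumbers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a HyperStack needs at least one frame")
        shape = self.frames[0].shape
        geom = self.frames[0].geometry
        for f in self.frames:
            if f.shape != shape or f.geometry != geom:
                raise ValueError("all frames must share one grid shape and geometry")
        wn = np.array([f.wavenumber for f in self.frames], dtype=float)
        if not np.all(np.diff(wn) > 0):
            raise ValueError("frame wavenumbers must be strictly increasing")
        self.wavenumbers = wn

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    @property
    def geometry(self) -> VoxelGeometry:
        return self.frames[0].geometry

    def cube(self) -> np.ndarray:
        """The full 4D array ``(wavenumber, z, y, x)``."""
        return np.stack([f.intensities for f in self.frames], axis=0)


@dataclass
class LipidDroplet:
    """One labeled 3D connected component of segmented lipid-droplet voxels.

    ``mean_unsaturation`` is the 3010/2900 ratio averaged over the droplet's
    valid voxels; ``None`` until attached (and ``None`` if no voxel had a
    usable denominator).  ``cell_id`` is ``None`` until droplets are assigned
    to cells.
    """

    label: int
    voxel_count: int
    volume: float
    centroid: tuple[float, float, float]  # (x, y, z) μm
    mean_unsaturation: float | None = None
    cell_id: int | None = None

    @property
    def measured(self) -> bool:
        return self.mean_unsaturation is not None


def read_stack(path: str | Path, wavenumber: float, geometry: VoxelGeometry) -> RamanChannelStack:
    """Read a multi-page grayscale TIFF as a ``(z, y, x)`` stack.

    Page order is taken as increasing z; no reordering heuristics are applied.
    Signed integer input is accepted (lock-in output can be negative before
    baseline handling); pixels are converted to float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image stack: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = list(tif.pages)
        if any(getattr(p, "samplesperpixel", 1) != 1 for p in pages):
            raise NonGrayscalePageError(
                f"{path}: pages must be single-channel grayscale images"
            )
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise InconsistentPageShapeError(
                f"{path}: inconsistent page shape {sorted(shapes)}"
            )
        data = tif.asarray()
    if data.ndim == 2:  # single-page file
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise NonGrayscalePageError(
            f"{path}: expected grayscale pages, got shape {data.shape}"
        )
    return RamanChannelStack(data.astype(np.float64), wavenumber, geometry)


def write_stack(volume: RamanChannelStack | np.ndarray, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per z-plane.

    ``RamanChannelStack`` intensities are written as float32; bare integer
    arrays (label volumes) keep an integer pixel type.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if isinstance(volume, RamanChannelStack):
        arr = volume.intensities.astype(np.float32)
    else:
        arr = np.asarray(volume)
        if arr.ndim != 3:
            raise ValueError("expected a 3D volume")
        if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
            arr = arr.astype(np.int32)
        else:
            arr = arr.astype(np.float32)
    # explicit photometric: narrow planes would otherwise be guessed as
    # multi-sample (RGB-like) pages on read
    tifffile.imwrite(path, arr, photometric="minisblack")


def _fmt(x: float | int | None) -> str:
    if x is None:
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_droplet_table(droplets: Sequence[LipidDroplet], path: str | Path) -> None:
    """Write droplets to CSV, one row per droplet, ordered by label id.

    Floats are written with ``repr`` so a round-trip recovers full precision.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    rows = sorted(droplets, key=lambda d: d.label)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DROPLET_TABLE_COLUMNS)
        for d in rows:
            writer.writerow(
                [
                    d.label,
                    d.voxel_count,
                    _fmt(d.volume),
                    _fmt(d.centroid[0]),
                    _fmt(d.centroid[1]),
                    _fmt(d.centroid[2]),
                    _fmt(d.mean_unsaturation),
                    _fmt(d.cell_id),
                ]
            )


def read_droplet_table(path: str | Path) -> list[LipidDroplet]:
    """Parse a droplet CSV written by :func:`write_droplet_table`."""
    path = Path(path)
    droplets: list[LipidDroplet] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != DROPLET_TABLE_COLUMNS:
            raise ValueError(f"{path}: not a droplet table (header {reader.fieldnames})")
        for row in reader:
            droplets.append(
                LipidDroplet(
                    label=int(row["label"]),
                    voxel_count=int(row["voxel_count"]),
                    volume=float(row["volume_um3"]),
                    centroid=(
                        float(row["centroid_x_um"]),
                        float(row["centroid_y_um"]),
                        float(row["centroid_z_um"]),
                    ),
                    mean_unsaturation=(
                        float(row["mean_unsaturation"]) if row["mean_unsaturation"] else None
                    ),
                    cell_id=int(row["cell_id"]) if row["cell_id"] else None,
                )
            )
    return droplets
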