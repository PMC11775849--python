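"""Synthetic two-channel SRS phantoms with known ground truth.

The generator emulates the acquisition this pipeline consumes: spherical
cells filled with cytoplasm, spherical lipid droplets of lognormal radius
with a per-droplet true unsaturation ratio, depth-dependent multiplicative
attenuation applied identically to both channels, a smooth illumination
field, and additive Gaussian noise (lock-in detection noise is approximately
Gaussian at these fluxes).  Droplet edges are rendered with partial-volume
weighting by 3× supersampling, which bounds volume quantisation error.

Everything is a pure function of (spec, seed): a fixed spec reproduces
bit-identical stacks and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_stacks import HyperStack, RamanChannelStack, VoxelGeometry

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "OvercrowdedSpecError",
    "generate_embryo_phantom",
    "generate_two_cell_phantom",
    "generate_calibration_series",
    "generate_hyperstack_phantom",
    "sample_droplet_population",
    "two_cell_spec",
]

_SUPERSAMPLE = 3


class OvercrowdedSpecError(RuntimeError):
    """Droplets could not be placed after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom study conditions.

    Intensities are in units of the droplet 2900 cm⁻¹ signal (= 1), so
    ``noise_sigma = 0.1`` is an SNR-10 acquisition; the 3010 channel's noise
    defaults to the same signal-to-noise ratio relative to its (weaker)
    droplet signal.  ``cytoplasm_intensity``
    is the cytoplasm 2900 level as a fraction of the droplet level, and
    ``cytoplasm_ratio`` its (lower) 3010/2900 ratio.  Droplet radii are
    lognormal; ``radius_unsat_corr`` imposes a Gaussian-copula correlation ρ
    between log radius and true unsaturation.  Attenuation multiplies both
    channels by exp(−z/attenuation_length).
    """

    grid_shape: tuple[int, int, int] = (40, 160, 160)  # (nz, ny, nx)
    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(0.3, 0.3, 1.0))
    cells: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((24.0, 24.0, 20.0), 20.0),
    )  # ((x, y, z) μm, radius μm)
    droplets_per_cell: int = 40
    droplet_radius_median: float = 1.1  # μm
    droplet_radius_sigma_log: float = 0.25
    unsat_mean: float = 0.30
    unsat_sigma: float = 0.05
    radius_unsat_corr: float = 0.0
    cytoplasm_intensity: float = 0.15
    cytoplasm_ratio: float = 0.20
    attenuation_length: float = 70.0  # μm; np.inf disables
    illumination_amplitude: float = 0.10
    noise_sigma: float = 0.10
    # 3010-channel noise; None scales noise_sigma by the typical 3010/2900
    # signal ratio (= unsat_mean), i.e. both channels are acquired at the
    # same SNR with respect to their own droplet signal
    noise_sigma_3010: float | None = None
    min_separation: float = 2.0  # μm of clearance between droplet surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.radius_unsat_corr) > 1:
            raise ValueError("|radius_unsat_corr| must be <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_sigma_3010 is not None and self.noise_sigma_3010 < 0:
            raise ValueError("noise_sigma_3010 must be >= 0")
        if not self.attenuation_length > 0:
            raise ValueError("attenuation_length must be > 0 (np.inf disables)")
        if self.droplet_radius_median <= 0:
            raise ValueError("droplet radii must be positive")
        nz, ny, nx = self.grid_shape
        g = self.geometry
        extent = (nx * g.dx, ny * g.dy, nz * g.dz)
        for center, radius in self.cells:
            if radius <= 0:
                raise ValueError("cell radii must be positive")
            for c, e in zip(center, extent):
                if c - radius < -g.dx or c + radius > e + g.dx:
                    raise ValueError(f"cell at {center} (r={radius}) exceeds the grid")


@dataclass
class PhantomGroundTruth:
    """Truth tables paired with the generated stacks.

    ``droplets`` columns: id, x/y/z_um, radius_um, true_unsaturation,
    cell_id, analytic_volume_um3, voxelized_volume_um3.
    ``true_cell_labels`` (two-cell phantoms only) assigns each voxel its true
    cell by the nearest-cell-centre rule in the lens region.
    """

    droplets: pd.DataFrame
    cells: pd.DataFrame
    seed: int
    spec: PhantomSpec
    true_cell_labels: np.ndarray | None = None


def sample_droplet_population(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample per-droplet (radius, unsaturation) pairs for every cell.

    Radii are lognormal around ``droplet_radius_median``; unsaturation is
    normal (clipped to stay positive); a Gaussian copula couples the two
    with correlation ``radius_unsat_corr``.  Placement is not done here.
    """
    rows = []
    rho = spec.radius_unsat_corr
    for cell_id in range(1, len(spec.cells) + 1):
        n = spec.droplets_per_cell
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n)
        radii = spec.droplet_radius_median * np.exp(spec.droplet_radius_sigma_log * z1)
        unsat = np.clip(spec.unsat_mean + spec.unsat_sigma * z2, 0.02, None)
        for r, u in zip(radii, unsat):
            rows.append({"cell_id": cell_id, "radius_um": float(r), "true_unsaturation": float(u)})
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    df["analytic_volume_um3"] = 4.0 / 3.0 * np.pi * df["radius_um"] ** 3
    return df


def _place_droplets(
    spec: PhantomSpec, pop: pd.DataFrame, rng: np.random.Generator, max_tries: int = 2000
) -> pd.DataFrame:
    """Draw non-overlapping droplet centres inside their cells."""
    placed_xyz: list[np.ndarray] = []
    placed_r: list[float] = []
    xs, ys, zs = [], [], []
    for row in pop.itertuples():
        (cx, cy, cz), cr = spec.cells[row.cell_id - 1]
        r = row.radius_um
        max_r = cr - r - 0.5
        if max_r <= 0:
            raise OvercrowdedSpecError(f"droplet r={r:.2f} μm does not fit cell r={cr} μm")
        for _ in range(max_tries):
            # uniform in the sphere of radius max_r
            v = rng.standard_normal(3)
            v *= max_r * rng.uniform() ** (1 / 3) / np.linalg.norm(v)
            p = np.array([cx, cy, cz]) + v
            ok = all(
                np.linalg.norm(p - q) >= r + rq + spec.min_separation
                for q, rq in zip(placed_xyz, placed_r)
            )
            if ok:
                break
        else:
            raise OvercrowdedSpecError(
                f"could not place droplet {row.id} after {max_tries} tries"
            )
        placed_xyz.append(p)
        placed_r.append(r)
        xs.append(p[0])
        ys.append(p[1])
        zs.append(p[2])
    out = pop.copy()
    out["x_um"], out["y_um"], out["z_um"] = xs, ys, zs
    return out


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = spec.grid_shape
    g = spec.geometry
    return (
        np.arange(nz) * g.dz,
        np.arange(ny) * g.dy,
        np.arange(nx) * g.dx,
    )


def _sphere_occupancy(
    spec: PhantomSpec, center: tuple[float, float, float], radius: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Partial-volume occupancy of a sphere over its bounding box.

    Voxels whose centre is well inside/outside get 1/0 analytically; the
    boundary shell is supersampled 3× per axis.
    """
    g = spec.geometry
    nz, ny, nx = spec.grid_shape
    cx, cy, cz = center
    z0 = max(int(np.floor((cz - radius) / g.dz)) - 1, 0)
    z1 = min(int(np.ceil((cz + radius) / g.dz)) + 2, nz)
    y0 = max(int(np.floor((cy - radius) / g.dy)) - 1, 0)
    y1 = min(int(np.ceil((cy + radius) / g.dy)) + 2, ny)
    x0 = max(int(np.floor((cx - radius) / g.dx)) - 1, 0)
    x1 = min(int(np.ceil((cx + radius) / g.dx)) + 2, nx)
    box = (slice(z0, z1), slice(y0, y1), slice(x0, x1))

    zc = (np.arange(z0, z1) * g.dz - cz)[:, None, None]
    yc = (np.arange(y0, y1) * g.dy - cy)[None, :, None]
    xc = (np.arange(x0, x1) * g.dx - cx)[None, None, :]
    dist = np.sqrt(zc * zc + yc * yc + xc * xc)
    half_diag = 0.5 * np.sqrt(g.dx**2 + g.dy**2 + g.dz**2)
    occ = np.zeros(dist.shape)
    occ[dist <= radius - half_diag] = 1.0
    shell = (dist > radius - half_diag) & (dist < radius + half_diag)
    if shell.any():
        s = _SUPERSAMPLE
        offs_z = (np.arange(s) + 0.5) / s - 0.5
        sz, sy, sx = np.meshgrid(offs_z * g.dz, offs_z * g.dy, offs_z * g.dx, indexing="ij")
        sub = np.stack([sz.ravel(), sy.ravel(), sx.ravel()], axis=1)  # (27, 3)
        idx = np.argwhere(shell)
        pts = np.column_stack(
            [
                (idx[:, 0] + z0) * g.dz - cz,
                (idx[:, 1] + y0) * g.dy - cy,
                (idx[:, 2] + x0) * g.dx - cx,
            ]
        )
        d2 = (
            (pts[:, None, 0] + sub[None, :, 0]) ** 2
            + (pts[:, None, 1] + sub[None, :, 1]) ** 2
            + (pts[:, None, 2] + sub[None, :, 2]) ** 2
        )
        occ[shell] = np.mean(d2 <= radius * radius, axis=1)
    return box, occ


def _illumination(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly positive in-plane illumination field, shape (ny, nx)."""
    nz, ny, nx = spec.grid_shape
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    x = np.linspace(0, 2 * np.pi, nx, endpoint=False)
    y = np.linspace(0, 2 * np.pi, ny, endpoint=False)
    return 1.0 + spec.illumination_amplitude * np.outer(
        np.sin(y + phy), np.sin(x + phx)
    )


def _render(
    spec: PhantomSpec, placed: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clean 2900/3010 volumes plus per-droplet voxelized volumes."""
    shape = spec.grid_shape
    cell_occ = np.zeros(shape)
    for center, radius in spec.cells:
        box, occ = _sphere_occupancy(spec, center, radius)
        np.maximum(cell_occ[box], occ, out=cell_occ[box])

    drop_occ = np.zeros(shape)
    drop_unsat_occ = np.zeros(shape)
    voxelized = np.zeros(len(placed))
    g = spec.geometry
    for i, row in enumerate(placed.itertuples()):
        box, occ = _sphere_occupancy(spec, (row.x_um, row.y_um, row.z_um), row.radius_um)
        drop_occ[box] += occ
        drop_unsat_occ[box] += occ * row.true_unsaturation
        voxelized[i] = occ.sum() * g.voxel_volume
    np.clip(drop_occ, 0.0, 1.0, out=drop_occ)

    cyto = spec.cytoplasm_intensity * cell_occ * (1.0 - drop_occ)
    i2900 = cyto + drop_occ
    i3010 = spec.cytoplasm_ratio * cyto + drop_unsat_occ
    return i2900, i3010, voxelized


def _acquire(
    spec: PhantomSpec,
    clean: np.ndarray,
    rng: np.random.Generator,
    illum: np.ndarray,
    sigma: float | None = None,
) -> np.ndarray:
    nz = spec.grid_shape[0]
    z_um = np.arange(nz) * spec.geometry.dz
    atten = np.exp(-z_um / spec.attenuation_length)[:, None, None]
    out = clean * atten * illum[None, :, :]
    sigma = spec.noise_sigma if sigma is None else sigma
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return out


def _sigma_3010(spec: PhantomSpec) -> float:
    if spec.noise_sigma_3010 is not None:
        return spec.noise_sigma_3010
    return spec.noise_sigma * spec.unsat_mean


def _cells_table(spec: PhantomSpec) -> pd.DataFrame:
    rows = []
    for i, (center, radius) in enumerate(spec.cells, start=1):
        rows.append(
            {
                "id": i,
                "x_um": center[0],
                "y_um": center[1],
                "z_um": center[2],
                "radius_um": radius,
                "volume_um3": 4.0 / 3.0 * np.pi * radius**3,
            }
        )
    return pd.DataFrame(rows)


def generate_embryo_phantom(
    spec: PhantomSpec,
) -> tuple[RamanChannelStack, RamanChannelStack, PhantomGroundTruth]:
    """Generate the two co-registered channel stacks plus ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pop = sample_droplet_population(spec, rng)
    placed = _place_droplets(spec, pop, rng)
    i2900, i3010, voxelized = _render(spec, placed, rng)
    illum = _illumination(spec, rng)
    noisy2900 = _acquire(spec, i2900, rng, illum)
    noisy3010 = _acquire(spec, i3010, rng, illum, sigma=_sigma_3010(spec))
    placed = placed.assign(voxelized_volume_um3=voxelized)
    truth = PhantomGroundTruth(
        droplets=placed[
            [
                "id",
                "x_um",
                "y_um",
                "z_um",
                "radius_um",
                "true_unsaturation",
                "cell_id",
                "analytic_volume_um3",
                "voxelized_volume_um3",
            ]
        ],
        cells=_cells_table(spec),
        seed=spec.seed,
        spec=spec,
    )
    return (
        RamanChannelStack(noisy2900, 2900.0, spec.geometry),
        RamanChannelStack(noisy3010, 3010.0, spec.geometry),
        truth,
    )


def two_cell_spec(
    radius: float = 25.0,
    distance: float = 40.0,
    droplets_per_cell: int = 20,
    **overrides,
) -> PhantomSpec:
    """Standard two-overlapping-spheres fixture (2-cell-stage morphology)."""
    margin = 3.0
    x1 = margin + radius
    x2 = x1 + distance
    y = margin + radius
    z = 1.0 + radius
    g = VoxelGeometry(0.3, 0.3, 1.0)
    nx = int(np.ceil((x2 + radius + margin) / g.dx))
    ny = int(np.ceil((2 * y) / g.dy))
    nz = int(np.ceil((2 * z) / g.dz)) + 1
    base = PhantomSpec(
        grid_shape=(nz, ny, nx),
        geometry=g,
        cells=(((x1, y, z), radius), ((x2, y, z), radius)),
        droplets_per_cell=droplets_per_cell,
    )
    return replace(base, **overrides) if overrides else base


def generate_two_cell_phantom(
    spec: PhantomSpec,
) -> tuple[RamanChannelStack, RamanChannelStack, PhantomGroundTruth]:
    """Two-cell phantom: as the embryo phantom, plus a true-cell label volume.

    Requires exactly 2 overlapping cells (centre distance < r₁ + r₂ — no
    overlap means no neck concavity to detect).  Each voxel inside the union
    of the spheres gets its true cell by the nearest-cell-centre rule in the
    lens region.
    """
    if len(spec.cells) != 2:
        raise ValueError("two-cell phantom needs exactly 2 cells")
    (c1, r1), (c2, r2) = spec.cells
    d = float(np.linalg.norm(np.subtract(c1, c2)))
    if d >= r1 + r2:
        raise ValueError(
            f"cells do not overlap (distance {d:.1f} >= r1+r2 = {r1 + r2:.1f})"
        )
    s2900, s3010, truth = generate_embryo_phantom(spec)
    zc, yc, xc = _voxel_centers(spec)
    d1 = np.sqrt(
        (zc[:, None, None] - c1[2]) ** 2
        + (yc[None, :, None] - c1[1]) ** 2
        + (xc[None, None, :] - c1[0]) ** 2
    )
    d2 = np.sqrt(
        (zc[:, None, None] - c2[2]) ** 2
        + (yc[None, :, None] - c2[1]) ** 2
        + (xc[None, None, :] - c2[0]) ** 2
    )
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    in1, in2 = d1 <= r1, d2 <= r2
    labels[in1 & ~in2] = 1
    labels[in2 & ~in1] = 2
    lens = in1 & in2
    labels[lens] = np.where(d1[lens] <= d2[lens], 1, 2)
    truth.true_cell_labels = labels
    return s2900, s3010, truth


def generate_calibration_series(
    cc_counts: list[int],
    slope: float,
    intercept: float,
    noise_sigma: float,
    seed: int,
) -> list[tuple[int, float]]:
    """Seeded (C=C count, ratio) pairs on a line with Gaussian scatter."""
    if slope < 0 or intercept < 0:
        raise ValueError("slope and intercept must be >= 0")
    rng = np.random.default_rng(seed)
    return [
        (int(cc), float(slope * cc + intercept + rng.normal(0.0, noise_sigma)))
        for cc in cc_counts
    ]


def generate_hyperstack_phantom(
    spec: PhantomSpec,
    peaks: list[tuple[float, float, str]] | None = None,
    wavenumbers: np.ndarray | None = None,
) -> HyperStack:
    """Hyperspectral phantom: per-voxel spectrum on a 2800–3050 cm⁻¹ grid.

    Each peak is (center cm⁻¹, Gaussian width cm⁻¹, channel), with channel
    "ch" scaling by the clean 2900 density and "unsat" by the clean 3010
    density (droplet unsaturation × density).  Spatial layout, attenuation,
    illumination, and noise match the two-channel phantom.  Intended for
    small grids; memory grows with frames × voxels.
    """
    if wavenumbers is None:
        wavenumbers = np.arange(2800.0, 3051.0, 5.0)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if peaks is None:
        peaks = [(2900.0, 30.0, "ch"), (3010.0, 15.0, "unsat")]
    for center, width, channel in peaks:
        if not (wavenumbers[0] <= center <= wavenumbers[-1]):
            raise ValueError(f"peak center {center} outside the sampled range")
        if width <= 0 or channel not in ("ch", "unsat"):
            raise ValueError("malformed peak model")
    rng = np.random.default_rng(spec.seed)
    pop = sample_droplet_population(spec, rng)
    placed = _place_droplets(spec, pop, rng)
    i2900, i3010, _ = _render(spec, placed, rng)
    illum = _illumination(spec, rng)
    amp = {"ch": i2900, "unsat": i3010}
    frames = []
    for wn in wavenumbers:
        clean = np.zeros(spec.grid_shape)
        for center, width, channel in peaks:
            clean = clean + amp[channel] * np.exp(-0.5 * ((wn - center) / width) ** 2)
        frames.append(
            RamanChannelStack(_acquire(spec, clean, rng, illum), wn, spec.geometry)
        )
    return HyperStack(frames)
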