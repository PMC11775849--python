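import numpy as np
import pytest

from srslipid.cell_segmentation import (
    CellSegmentationParams,
    NoCellFoundError,
    NotTwoCellError,
    assign_droplets_to_cells,
    detect_concave_points,
    segment_cell_mask,
    split_two_cells,
    summarize_cells,
    CellLabelVolume,
)
from srslipid.io_stacks import LipidDroplet, VoxelGeometry

from conftest import DEFAULT_GEOMETRY, make_stack


def circle_polygon(radius, center=(0.0, 0.0), n=200):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def two_circle_union_outline(r, d, n=1200):
    """Outline of two overlapping circles with centers (±d/2, 0)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = []
    for cx in (-d / 2, d / 2):
        for x, y in zip(cx + r * np.cos(t), r * np.sin(t)):
            # keep arcs outside the other circle
            other = (x + cx) ** 2 + y**2 if cx > 0 else (x - d / 2) ** 2 + y**2
            if (x - (-cx)) ** 2 + y**2 >= r**2:
                pts.append((x, y))
    pts = np.array(pts)
    # order by angle around the origin to form a closed outline
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    return pts[np.argsort(ang)]


class TestDetectConcavePoints:
    def test_convex_circle_has_none(self):
        assert detect_concave_points(circle_polygon(50.0), arm_length=5) == []

    def test_rectangle_has_none(self):
        # perimeter resampled densely so corners stay convex at arm scale
        xs = np.linspace(0, 40, 41)
        top = [(x, 0.0) for x in xs]
        right = [(40.0, y) for y in np.linspace(1, 20, 20)]
        bottom = [(x, 20.0) for x in xs[::-1]]
        left = [(0.0, y) for y in np.linspace(19, 1, 19)]
        rect = np.array(top + right + bottom + left)
        assert detect_concave_points(rect, arm_length=5) == []

    def test_two_circle_union_cusps_at_analytic_positions(self):
        r, d = 40.0, 60.0
        outline = two_circle_union_outline(r, d)
        points = detect_concave_points(outline, arm_length=5)
        assert len(points) >= 2
        pos = np.array([p.position for p in points])
        # analytic cusps: x = 0, y = ±sqrt(r² − (d/2)²)
        y_cusp = np.sqrt(r**2 - (d / 2) ** 2)
        top = pos[pos[:, 1] > 0]
        bottom = pos[pos[:, 1] < 0]
        assert len(top) and len(bottom)
        for cluster, yc in ((top, y_cusp), (bottom, -y_cusp)):
            center = cluster.mean(axis=0)
            assert abs(center[0]) < 3.0
            assert abs(center[1] - yc) < 3.0

    def test_all_detected_angles_reflex(self):
        outline = two_circle_union_outline(40.0, 60.0)
        for p in detect_concave_points(outline, arm_length=5):
            assert p.concavity_angle > np.pi

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            detect_concave_points(circle_polygon(10.0, n=10), arm_length=5)


def two_sphere_mask(nz=20, ny=80, nx=120, r=28, d=44, z_r=8):
    """Two overlapping ellipsoid-ish cells (flattened in z for a small grid)."""
    zz, yy, xx = np.indices((nz, ny, nx)).astype(float)
    c1 = (nz / 2, ny / 2, nx / 2 - d / 2)
    c2 = (nz / 2, ny / 2, nx / 2 + d / 2)
    m1 = ((zz - c1[0]) / z_r) ** 2 + ((yy - c1[1]) / r) ** 2 + ((xx - c1[2]) / r) ** 2 <= 1
    m2 = ((zz - c2[0]) / z_r) ** 2 + ((yy - c2[1]) / r) ** 2 + ((xx - c2[2]) / r) ** 2 <= 1
    return m1 | m2, m1, m2


class TestSplitTwoCells:
    def test_split_partitions_mask_exactly(self, geometry):
        mask, m1, m2 = two_sphere_mask()
        cells = split_two_cells(mask, geometry)
        labels = cells.labels
        assert ((labels > 0) == mask).all()
        assert set(np.unique(labels)) == {0, 1, 2}
        vols = cells.cell_volumes
        assert vols[1] + vols[2] == pytest.approx(mask.sum() * geometry.voxel_volume)

    def test_split_separates_the_two_bodies(self, geometry):
        mask, m1, m2 = two_sphere_mask()
        labels = split_two_cells(mask, geometry).labels
        only1 = m1 & ~m2
        only2 = m2 & ~m1
        acc1 = max((labels[only1] == 1).mean(), (labels[only1] == 2).mean())
        acc2 = max((labels[only2] == 1).mean(), (labels[only2] == 2).mean())
        assert acc1 > 0.95 and acc2 > 0.95
        assert labels[only1].max() != labels[only2].max() or (
            (labels[only1] == labels[only1][0]).all()
            and not (labels[only2] == labels[only1][0]).all()
        )

    def test_symmetric_dumbbell_cut_near_waist(self, geometry):
        mask, _, _ = two_sphere_mask()
        cells = split_two_cells(mask, geometry)
        v = sorted(cells.cell_volumes.values())
        assert abs(v[1] - v[0]) / sum(v) < 0.02  # symmetric halves

    def test_deterministic_labels(self, geometry):
        mask, _, _ = two_sphere_mask()
        a = split_two_cells(mask, geometry).labels
        b = split_two_cells(mask, geometry).labels
        np.testing.assert_array_equal(a, b)

    def test_single_convex_sphere_not_two_cells(self, geometry):
        zz, yy, xx = np.indices((16, 60, 60)).astype(float)
        mask = ((zz - 8) / 6) ** 2 + ((yy - 30) / 22) ** 2 + ((xx - 30) / 22) ** 2 <= 1
        with pytest.raises(NotTwoCellError):
            split_two_cells(mask, geometry)


class TestSegmentCellMask:
    def test_all_zero_stack_raises(self):
        with pytest.raises(NoCellFoundError):
            segment_cell_mask(make_stack(np.zeros((4, 30, 30))))

    def test_interior_holes_filled(self):
        vol = np.zeros((6, 60, 60))
        yy, xx = np.indices((60, 60)).astype(float)
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
        hole = (yy - 30) ** 2 + (xx - 30) ** 2 <= 5**2
        for z in range(1, 5):
            vol[z][disk] = 1.0
            vol[z][hole] = 0.0  # dark vacuole inside the cell
        params = CellSegmentationParams(smooth_sigma=0.0, opening_radius=0.3)
        mask = segment_cell_mask(make_stack(vol), params)
        assert mask[2][hole].all()

    def test_largest_component_kept(self):
        vol = np.zeros((4, 60, 60))
        vol[1:3, 10:40, 10:40] = 1.0
        vol[1, 50:54, 50:54] = 1.0  # small satellite blob
        params = CellSegmentationParams(smooth_sigma=0.0, opening_radius=0.0)
        mask = segment_cell_mask(make_stack(vol), params)
        assert mask[1:3, 10:40, 10:40].all()
        assert not mask[1, 50:54, 50:54].any()


class TestAssignDroplets:
    def _cells(self):
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[:, :, :5] = 1
        labels[:, :, 5:] = 2
        labels[:, :, 4:6] = 0  # background strip between the cells
        return CellLabelVolume(labels=labels, geometry=DEFAULT_GEOMETRY)

    def test_interior_droplet_gets_its_cell(self):
        cells = self._cells()
        d = LipidDroplet(1, 4, 0.36, (0.6, 1.5, 2.0))  # x=2px -> cell 1
        (out,) = assign_droplets_to_cells([d], cells)
        assert out.cell_id == 1

    def test_background_centroid_snaps_to_nearest_cell_within_2(self):
        cells = self._cells()
        d = LipidDroplet(1, 4, 0.36, (1.35, 1.5, 2.0))  # x=4.5px: on the strip
        (out,) = assign_droplets_to_cells([d], cells)
        assert out.cell_id in (1, 2)

    def test_far_from_cells_unassigned(self):
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[:, :, 7:] = 1
        cells = CellLabelVolume(labels=labels, geometry=DEFAULT_GEOMETRY)
        d = LipidDroplet(1, 4, 0.36, (0.3, 1.5, 2.0))  # x=1px, >2 voxels away
        (out,) = assign_droplets_to_cells([d], cells)
        assert out.cell_id is None

    def test_summary_table_contents(self):
        cells = self._cells()
        droplets = [
            LipidDroplet(1, 4, 1.0, (0.6, 1.5, 2.0), 0.2, 1),
            LipidDroplet(2, 4, 3.0, (0.6, 2.1, 2.0), 0.4, 1),
            LipidDroplet(3, 4, 2.0, (2.4, 1.5, 2.0), 0.3, 2),
        ]
        table = summarize_cells(cells, droplets)
        row1 = table[table.cell_id == 1].iloc[0]
        assert row1.ld_count == 2
        assert row1.mean_unsaturation == pytest.approx(0.3)
        assert row1.weighted_unsaturation == pytest.approx((0.2 + 3 * 0.4) / 4)
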