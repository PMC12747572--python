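"""Morphometry: preprocessing, segmentation, descriptors, QC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliascope import morphology as m
from gliascope import synthetic as s
from gliascope.errors import DegenerateInputError
from gliascope.images import VolumetricImage


def stack_from_channels(cell, nucleus, pitch=1.0):
    return VolumetricImage(
        data=np.stack([cell, nucleus]).astype(float),
        voxel_pitch_um=(pitch,) * 3,
        channel_names=("membrane", "nucleus"),
    )


def ellipsoid_coords(semi_axes, center=(0, 0, 0)):
    """Voxel coordinates of an axis-aligned ellipsoid (independent of the pipeline)."""
    a = np.asarray(semi_axes, float)
    c = np.asarray(center, float)
    lo = np.floor(c - a).astype(int)
    hi = np.ceil(c + a).astype(int) + 1
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    inside = np.sum(((pts - c) / a) ** 2, axis=1) <= 1.0
    return pts[inside] - lo  # shift to non-negative indices


class TestPreprocess:
    def test_bright_cube_recovered_exactly(self):
        cell = np.full((40, 40, 40), 10.0)
        cell[10:30, 10:30, 10:30] = 200.0
        nuc = np.full((40, 40, 40), 10.0)
        nuc[18:22, 18:22, 18:22] = 200.0
        cfg = m.MorphConfig(blur_sigma_px=0.0, downsample_factor=1)
        cloud, _ = m.preprocess_stack(stack_from_channels(cell, nuc), cfg)
        expected = {(z, y, x) for z in range(10, 30) for y in range(10, 30) for x in range(10, 30)}
        assert set(map(tuple, cloud.coordinates)) == expected

    def test_all_zero_stack_is_degenerate(self):
        zeros = np.zeros((10, 10, 10))
        with pytest.raises(DegenerateInputError):
            m.preprocess_stack(stack_from_channels(zeros, zeros), m.MorphConfig())

    def test_downsample_matches_reference_block_vote(self):
        """Blur + threshold + 2x block vote against a naive loop reference."""
        cell = np.full((48, 48, 48), 10.0)
        cell[4:44, 4:44, 4:44] = 200.0  # 40^3 cube
        nuc = cell.copy()
        cfg = m.MorphConfig(blur_sigma_px=2.0, downsample_factor=2)
        cloud, _ = m.preprocess_stack(stack_from_channels(cell, nuc), cfg)

        from scipy.ndimage import gaussian_filter
        from skimage.filters import threshold_otsu

        norm = (cell - cell.min()) / (cell.max() - cell.min())
        blurred = gaussian_filter(norm, 2.0)
        binary = blurred > threshold_otsu(blurred)
        ref = set()
        for z in range(24):
            for y in range(24):
                for x in range(24):
                    block = binary[2*z:2*z+2, 2*y:2*y+2, 2*x:2*x+2]
                    if block.sum() > 4:
                        ref.add((z, y, x))
        assert set(map(tuple, cloud.coordinates)) == ref
        # a 40-voxel cube pools to ~20 units per edge (1-voxel blur halo allowed)
        assert abs(len(ref) - 20**3) < 3 * 21**2


def brute_force_dbscan(points, eps, min_samples):
    """Reference density clustering: BFS over eps-neighbourhood graph from core points."""
    pts = np.asarray(points, float)
    n = len(pts)
    d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
    neighbors = [set(np.flatnonzero(d2[i] <= eps**2)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = [-1] * n
    cur = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack, labels[i] = [i], cur
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cur
                    if core[k]:
                        stack.append(k)
        cur += 1
    return labels, cur


class TestSegmentation:
    def test_two_separated_blobs(self):
        a = np.argwhere(np.ones((5, 5, 5), bool))
        b = a + [0, 0, 25]
        cloud = m.VoxelCloud(np.vstack([a, b]))
        cells = m.segment_cells(cloud, m.MorphConfig(dbscan_eps=2, dbscan_min_samples=10))
        assert len(cells) == 2

    def test_single_blob(self):
        cloud = m.VoxelCloud(np.argwhere(np.ones((6, 6, 6), bool)))
        assert len(m.segment_cells(cloud, m.MorphConfig())) == 1

    def test_lone_voxel_matches_brute_force_noise_labelling(self):
        blob = np.argwhere(np.ones((5, 5, 5), bool))
        lone = np.array([[2, 2, 15]])
        pts = np.vstack([blob, lone])
        cfg = m.MorphConfig(dbscan_eps=2, dbscan_min_samples=5)
        cells = m.segment_cells(m.VoxelCloud(pts), cfg)
        labels, n_clusters = brute_force_dbscan(pts, 2, 5)
        assert len(cells) == n_clusters == 1
        assert labels[-1] == -1  # reference agrees the lone voxel is noise
        total = sum(c.volume_units for c in cells)
        assert total == len(blob)

    def test_empty_cloud_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = m.segment_cells(m.VoxelCloud(np.empty((0, 3))), m.MorphConfig())
        assert out == []

    def test_output_order_is_deterministic(self):
        rng = np.random.default_rng(0)
        a = np.argwhere(np.ones((4, 4, 4), bool))
        pts = np.vstack([a, a + [0, 20, 0], a + [20, 0, 0]])
        cfg = m.MorphConfig(dbscan_min_samples=5)
        first = m.segment_cells(m.VoxelCloud(pts), cfg)
        shuffled = pts[rng.permutation(len(pts))]
        second = m.segment_cells(m.VoxelCloud(shuffled), cfg)
        for c1, c2 in zip(first, second):
            np.testing.assert_allclose(c1.centroid, c2.centroid)


class TestVolumetricFilters:
    def make_cells(self, volumes):
        out = []
        for v in volumes:
            # a 1-voxel-high slab of v voxels
            coords = np.array([[0, 0, x] for x in range(v)])
            out.append(m.make_cell(coords))
        return out

    @pytest.mark.parametrize(
        "volume,kept", [(49, False), (50, True), (51, True)]
    )
    def test_cell_volume_cutoff_is_strict_below(self, volume, kept):
        cells = self.make_cells([volume])
        kept_cells, _ = m.filter_components(cells, [], m.MorphConfig())
        assert (len(kept_cells) == 1) is kept

    @pytest.mark.parametrize("volume,kept", [(4, False), (5, True)])
    def test_nucleus_volume_cutoff(self, volume, kept):
        nuclei = self.make_cells([volume])
        _, kept_nuclei = m.filter_components([], nuclei, m.MorphConfig())
        assert (len(kept_nuclei) == 1) is kept


class TestNucleusMatching:
    def test_containment_wins(self):
        cell = m.make_cell(np.argwhere(np.ones((10, 10, 10), bool)))
        nuc = m.make_cell(np.argwhere(np.ones((2, 2, 2), bool)) + [4, 4, 4])
        assert m.match_nuclei([cell], [nuc]) == [(0, 0)]

    def test_equidistant_tie_breaks_to_lower_cell_id(self):
        c0 = m.make_cell(np.argwhere(np.ones((3, 3, 3), bool)))
        c1 = m.make_cell(np.argwhere(np.ones((3, 3, 3), bool)) + [0, 0, 20])
        nuc = m.make_cell(np.array([[1, 1, 11]]))  # midway, contained in neither
        matches = m.match_nuclei([c0, c1], [nuc])
        assert matches[0] == (0, 0)
        assert matches[1] == (1, None)

    def test_out_of_range_cell_left_unmatched(self):
        cell = m.make_cell(np.argwhere(np.ones((3, 3, 3), bool)))
        far = m.make_cell(np.array([[0, 0, 500]]))
        matches = m.match_nuclei([cell], [far], m.MorphConfig())
        assert matches == [(0, None)]


class TestDescriptors:
    def test_aspect_ratio_definition_and_degenerate_voxel(self):
        slab = m.make_cell(np.array([[0, y, x] for y in range(20) for x in range(10)]))
        assert m.aspect_ratio(slab) == pytest.approx(2.0)
        single = m.make_cell(np.array([[0, 0, 0]]))
        assert m.aspect_ratio(single) == 1.0

    def test_voxelized_sphere_is_round(self):
        cell = m.make_cell(ellipsoid_coords((8, 8, 8)))
        assert m.aspect_ratio(cell) == pytest.approx(1.0, abs=0.07)

    @pytest.mark.parametrize(
        "ry,rx,expected",
        [(10, 10, 1.0), (4, 2, 0.8), (20, 2, 20 / 101)],
    )
    def test_circularity_ellipse_mode(self, ry, rx, expected):
        cell = m.make_cell(np.array([[0, y, x] for y in range(ry) for x in range(rx)]))
        assert m.circularity(cell) == pytest.approx(expected, abs=1e-12)

    @given(
        ry=st.integers(min_value=1, max_value=60),
        rx=st.integers(min_value=1, max_value=60),
    )
    def test_circularity_bounds_and_symmetry(self, ry, rx):
        cell = m.make_cell(np.array([[0, y, x] for y in range(ry) for x in range(rx)]))
        swapped = m.make_cell(np.array([[0, y, x] for y in range(rx) for x in range(ry)]))
        c = m.circularity(cell)
        assert 0 < c <= 1
        assert (c == 1) == (rx == ry)
        assert m.circularity(swapped) == pytest.approx(c, rel=1e-12)
        assert m.aspect_ratio(swapped) == pytest.approx(1 / m.aspect_ratio(cell))

    def test_centroid_distance_345(self):
        cell = m.make_cell(np.array([[0, 0, 0]]))
        nuc = m.make_cell(np.array([[0, 3, 4]]))
        units, um = m.centroid_distance(cell, nuc, m.MorphConfig(unit_to_um=0.62))
        assert units == pytest.approx(5.0)
        assert um == pytest.approx(3.1)

    def test_solidity_of_convex_box_is_one(self):
        box = m.make_cell(np.argwhere(np.ones((3, 4, 5), bool)))
        assert m.solidity(box) == pytest.approx(1.0, abs=1e-12)

    def test_solidity_of_plus_sign_prism(self):
        # 5 unit squares extruded by one voxel: hull is an octagon of area 7
        coords = np.array([[0, 1, 0], [0, 1, 1], [0, 1, 2], [0, 0, 1], [0, 2, 1]])
        assert m.solidity(m.make_cell(coords)) == pytest.approx(1.4, abs=1e-12)

    def test_solidity_at_least_one_for_ellipsoids(self):
        for semi in [(4, 6, 9), (3, 3, 12), (7, 7, 7)]:
            cell = m.make_cell(ellipsoid_coords(semi))
            assert m.solidity(cell) >= 1.0

    def test_ramification_of_square_projection(self):
        cell = m.make_cell(np.array([[0, y, x] for y in range(12) for x in range(12)]))
        assert m.ramification(cell) == pytest.approx(2 / math.sqrt(math.pi), abs=1e-12)

    def test_ramification_picks_max_area_projection(self):
        # 10 x 10 x 2 box: the Z projection (10 x 10) has the largest area
        box = m.make_cell(np.argwhere(np.ones((2, 10, 10), bool)))
        assert m.ramification(box) == pytest.approx(2 / math.sqrt(math.pi), abs=1e-12)

    def test_ramification_of_disk_is_unity(self):
        r = 30
        coords = np.array(
            [[0, y, x] for y in range(-r, r + 1) for x in range(-r, r + 1)
             if x * x + y * y <= r * r]
        ) + [0, r, r]
        assert m.ramification(m.make_cell(coords)) == pytest.approx(1.0, abs=0.03)


class TestQC:
    def make_record(self, cell_id, **overrides):
        base = dict(
            cell_id=cell_id, aspect_ratio=1.0, circularity=0.9,
            centroid_distance_units=2.0, centroid_distance_um=1.24,
            solidity=1.5, ramification=1.2, volume_units=100,
            nucleus_id=cell_id, qc_flags=set(),
        )
        base.update(overrides)
        return m.MorphologyRecord(**base)

    def test_out_of_range_centroid_distance_excluded(self):
        cells = [m.make_cell(np.argwhere(np.ones((4, 4, 4), bool)))]
        nuclei = [m.make_cell(np.array([[0, 0, 120]]))]
        recs = m.build_records(cells, nuclei, [(0, 0)], m.MorphConfig())
        assert "centroid_out_of_range" in recs[0].qc_flags
        kept, excluded = m.apply_qc(recs, m.MorphConfig())
        assert kept == [] and len(excluded) == 1

    def test_zero_variance_metric_is_grubbs_noop(self):
        recs = [self.make_record(i) for i in range(5)]
        kept, excluded = m.apply_qc(recs, m.MorphConfig())
        assert len(kept) == 5 and excluded == []

    def test_grubbs_flags_the_extreme_record(self):
        recs = [
            self.make_record(i, solidity=v, circularity=0.5 + 0.01 * i)
            for i, v in enumerate([8.0, 9.0, 10.0, 50.0])
        ]
        kept, excluded = m.apply_qc(recs, m.MorphConfig())
        assert [r.cell_id for r in excluded] == [3]
        assert "grubbs_outlier" in excluded[0].qc_flags
        assert len(kept) == 3

    def test_fewer_than_three_records_skips_grubbs(self):
        recs = [self.make_record(0), self.make_record(1)]
        with pytest.warns(UserWarning):
            kept, _ = m.apply_qc(recs, m.MorphConfig())
        assert len(kept) == 2


class TestPipelineRecovery:
    def test_zero_noise_recovery_of_truth(self, small_morph_scene):
        img, truth = small_morph_scene
        cfg = m.MorphConfig(downsample_factor=1, unit_to_um=0.62)
        cloud_c, cloud_n = m.preprocess_stack(img, cfg)
        cells = m.segment_cells(cloud_c, cfg)
        nuclei = m.segment_cells(cloud_n, cfg)
        cells, nuclei = m.filter_components(cells, nuclei, cfg)
        assert len(cells) == len(truth)
        matches = m.match_nuclei(cells, nuclei, cfg)
        assert all(ni is not None for _, ni in matches)
        recs = m.build_records(cells, nuclei, matches, cfg)
        for rec, t in zip(recs, sorted(truth, key=lambda t: t.center_um)):
            assert rec.aspect_ratio == pytest.approx(t.aspect_ratio, rel=0.10)
            assert rec.centroid_distance_units == pytest.approx(
                t.centroid_distance_um / 0.62, abs=1.0
            )

    def test_analyze_stack_is_deterministic(self, small_morph_scene):
        img, _ = small_morph_scene
        cfg = m.MorphConfig(downsample_factor=1)
        a, _ = m.analyze_stack(img, cfg)
        b, _ = m.analyze_stack(img, cfg)
        assert a.equals(b)
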