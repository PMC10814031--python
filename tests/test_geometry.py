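"""Segment tracing, crossings, normals, angles, and distance transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from needlepath import geometry
from needlepath.anatomy import AnatomyScene, LabeledVolume
from needlepath.errors import EmptyStructureError, GeometryError
from needlepath.geometry import (
    DistanceField,
    Segment,
    distance_transform,
    first_crossing,
    max_along_segment,
    min_along_segment,
    path_surface_angle,
    surface_normal,
    trace_segment,
)


def _slab_volume():
    labels = np.zeros((40, 20, 20), dtype=np.int16)
    labels[10:20, :, :] = 3  # 10 mm slab at 1 mm spacing
    return LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))


def test_trace_segment_reports_slab():
    vol = _slab_volume()
    seg = Segment((2, 10, 10), (35, 10, 10))
    samples = trace_segment(vol, seg, 0.5)
    labs = [lab for _, lab in samples]
    in_slab = [lab == 3 for lab in labs]
    assert sum(in_slab) >= 20
    # consecutive run
    first, last = in_slab.index(True), len(in_slab) - 1 - in_slab[::-1].index(True)
    assert all(in_slab[first : last + 1])


def test_trace_segment_background_only():
    vol = _slab_volume()
    seg = Segment((2, 2, 2), (8, 15, 15))
    assert all(lab == 0 for _, lab in trace_segment(vol, seg, 0.5))


def test_trace_segment_rejects_bad_inputs():
    vol = _slab_volume()
    with pytest.raises(GeometryError):
        trace_segment(vol, Segment((0, 0, 0), (100, 0, 0)), 0.5)  # endpoint outside
    with pytest.raises(GeometryError):
        trace_segment(vol, Segment((0, 0, 0), (5, 0, 0)), 2.0)  # step > spacing


def _sphere_volume(radius_mm, spacing_mm, label=5):
    n = int(round(2 * (radius_mm + 2.0) / spacing_mm)) | 1
    c = (n - 1) * spacing_mm / 2.0
    ax = np.arange(n) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    labels = np.where((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius_mm**2, label, 0).astype(np.int16)
    return LabeledVolume(labels=labels, spacing=(spacing_mm,) * 3, origin=(0, 0, 0)), c


class TestFirstCrossing:
    def test_ray_sphere_axis_aligned(self):
        # fine spacing so voxelization error stays below the 0.1 mm contract
        vol, c = _sphere_volume(radius_mm=8.0, spacing_mm=0.15)
        start = np.array([0.3, c, c])
        hit = first_crossing(vol, Segment(start, (c, c, c)), {5}, step_mm=0.15)
        expected = (c - start[0]) - 8.0
        assert abs(np.linalg.norm(hit - start) - expected) <= 0.1

    def test_ray_sphere_oblique(self):
        vol, c = _sphere_volume(radius_mm=6.0, spacing_mm=0.1)
        start = np.array([0.4, 1.0, 0.7])
        center = np.array([c, c, c])
        hit = first_crossing(vol, Segment(start, center), {5}, step_mm=0.1)
        expected = np.linalg.norm(center - start) - 6.0
        assert abs(np.linalg.norm(hit - start) - expected) <= 0.1

    def test_ray_plane(self):
        labels = np.zeros((60, 10, 10), dtype=np.int16)
        labels[30:, :, :] = 2  # half-space x >= 29.5 (label boundary between centers)
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))
        hit = first_crossing(vol, Segment((2, 5, 5), (55, 5, 5)), {2}, step_mm=1.0)
        assert abs(hit[0] - 29.5) <= 0.1

    def test_empty_label_set(self):
        vol = _slab_volume()
        assert first_crossing(vol, Segment((2, 5, 5), (35, 5, 5)), set(), 0.5) is None

    def test_start_inside_returns_start(self):
        vol = _slab_volume()
        start = np.array([15.0, 5.0, 5.0])
        hit = first_crossing(vol, Segment(start, (35, 5, 5)), {3}, 0.5)
        np.testing.assert_allclose(hit, start)


class TestSurfaceNormal:
    def _sphere_scene(self):
        vol, c = _sphere_volume(radius_mm=20.0, spacing_mm=1.0, label=3)
        vol.labels[vol.labels == 0] = 1  # fill background so mandatory roles bind
        vol.labels[tuple(int(c) for _ in range(3))] = 7
        scene = AnatomyScene(
            volume=vol, roles={"skin": (1,), "lung_target_lobe": (3,), "tumor": (7,)}
        )
        return scene, c

    def test_sphere_normals_radial(self, rng):
        scene, c = self._sphere_scene()
        center = np.array([c, c, c])
        for _ in range(25):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = center + 20.0 * d
            n = surface_normal(scene, "lung_target_lobe", p)
            ang = math.degrees(math.acos(np.clip(abs(float(n @ d)), 0, 1)))
            assert ang <= 5.0
            assert float(n @ d) > 0  # outward

    def test_half_space_normal(self):
        labels = np.ones((20, 20, 40), dtype=np.int16)
        labels[:, :, :20] = 3  # z < 19.5 is the structure
        labels[5, 5, 30] = 7
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))
        scene = AnatomyScene(
            volume=vol, roles={"skin": (1,), "lung_target_lobe": (3,), "tumor": (7,)}
        )
        n = surface_normal(scene, "lung_target_lobe", np.array([10.0, 10.0, 19.5]))
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-3)

    def test_deep_interior_raises(self):
        scene, c = self._sphere_scene()
        with pytest.raises(GeometryError):
            surface_normal(scene, "lung_target_lobe", np.array([c, c, c]))


class TestPathSurfaceAngle:
    @pytest.mark.parametrize(
        "direction,normal,expected",
        [
            ((0, 0, 1), (0, 0, 1), 90.0),  # perpendicular insertion
            ((1, 0, 0), (0, 0, 1), 0.0),  # tangential
            ((1 / math.sqrt(2), 0, 1 / math.sqrt(2)), (0, 0, 1), 45.0),
        ],
    )
    def test_analytic_angles(self, direction, normal, expected):
        assert path_surface_angle(direction, normal) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            path_surface_angle((0, 0, 0), (0, 0, 1))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_negation_invariance_and_range(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(size=3)
        n = r.normal(size=3)
        if np.linalg.norm(d) < 1e-6 or np.linalg.norm(n) < 1e-6:
            return
        a = path_surface_angle(d, n)
        assert 0.0 <= a <= 90.0
        assert path_surface_angle(-d, n) == pytest.approx(a)
        assert path_surface_angle(d, -n) == pytest.approx(a)


def _brute_force_distance(mask, spacing):
    pts = np.argwhere(mask) * spacing
    grid = np.argwhere(np.ones_like(mask)) * spacing
    d = cdist(grid, pts).min(axis=1)
    return d.reshape(mask.shape)


class TestDistanceTransform:
    def test_3_4_5_triangle(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[0, 0, 0] = 9
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))
        fld = distance_transform(vol, {9})
        assert fld.values[3, 4, 0] == pytest.approx(5.0)

    def test_anisotropic_spacing(self):
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[0, 0, 0] = 9
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1.25), origin=(0, 0, 0))
        fld = distance_transform(vol, {9})
        assert fld.values[0, 0, 4] == pytest.approx(5.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(4, 16, size=3))
            mask = rng.random(shape) < 0.1
            if not mask.any():
                mask[0, 0, 0] = True
            spacing = rng.uniform(0.5, 2.0, size=3)
            labels = np.where(mask, 9, 0).astype(np.int16)
            vol = LabeledVolume(labels=labels, spacing=spacing, origin=(0, 0, 0))
            fld = distance_transform(vol, {9})
            np.testing.assert_allclose(fld.values, _brute_force_distance(mask, spacing), atol=1e-9)

    def test_zero_on_obstacles_nonnegative_elsewhere(self, rng):
        mask = rng.random((12, 12, 12)) < 0.2
        mask[0, 0, 0] = True
        labels = np.where(mask, 9, 0).astype(np.int16)
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))
        fld = distance_transform(vol, {9})
        assert np.all(fld.values[mask] == 0)
        assert np.all(fld.values >= 0)

    def test_empty_obstacle_raises(self):
        vol = _slab_volume()
        with pytest.raises(EmptyStructureError):
            distance_transform(vol, {42})


class TestSegmentProjections:
    def _random_smooth_field(self, rng):
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(rng.random((24, 24, 24)), 2.0) * 50.0
        return DistanceField(values=vals, spacing=np.ones(3), origin=np.zeros(3))

    def test_min_through_obstacle_is_zero(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[8:12, 8:12, 8:12] = 9
        vol = LabeledVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))
        fld = distance_transform(vol, {9})
        seg = Segment((1, 10, 10), (18, 10, 10))
        assert min_along_segment(fld, seg, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_constant_field(self):
        fld = DistanceField(values=np.full((10, 10, 10), 7.5), spacing=np.ones(3), origin=np.zeros(3))
        seg = Segment((1, 1, 1), (8, 8, 8))
        assert min_along_segment(fld, seg, 0.5) == pytest.approx(7.5)
        assert max_along_segment(fld, seg, 0.5) == pytest.approx(7.5)

    def test_monotone_field_max_at_far_end(self):
        # distance from point C: the MIP of the segment E -> C equals |E - C|
        C = np.array([10.0, 10.0, 10.0])
        ax = np.arange(21.0)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = np.sqrt((X - C[0]) ** 2 + (Y - C[1]) ** 2 + (Z - C[2]) ** 2)
        fld = DistanceField(values=vals, spacing=np.ones(3), origin=np.zeros(3))
        E = np.array([2.0, 3.0, 4.0])
        got = max_along_segment(fld, Segment(E, C), 0.5)
        assert got == pytest.approx(np.linalg.norm(E - C), abs=0.5)

    def test_extrema_bound_all_samples_and_match_dense_sampling(self, rng):
        fld = self._random_smooth_field(rng)
        for _ in range(5):
            a = rng.uniform(2, 21, size=3)
            b = rng.uniform(2, 21, size=3)
            seg = Segment(a, b)
            lo = min_along_segment(fld, seg, 1.0)
            hi = max_along_segment(fld, seg, 1.0)
            dense_lo = min_along_segment(fld, seg, 0.1)
            dense_hi = max_along_segment(fld, seg, 0.1)
            assert lo >= dense_lo - 1e-9 and hi <= dense_hi + 1e-9
            # smooth field: coarse extrema close to the dense-sampling oracle
            assert lo == pytest.approx(dense_lo, abs=0.5)
            assert hi == pytest.approx(dense_hi, abs=0.5)


def test_occupancy_crossing_locates_subvoxel_boundary():
    labels = np.zeros((40, 10, 10), dtype=np.int16)
    labels[20:, :, :] = 1  # interface between centers 19 and 20 -> surface at 19.5
    occ = geometry.occupancy_from_mask(labels > 0, sigma_vox=0.0)
    seg = Segment((1.0, 5.0, 5.0), (35.0, 5.0, 5.0))
    t = geometry.occupancy_crossing(occ, np.ones(3), np.zeros(3), seg, step_mm=1.0)
    x = seg.point(t)[0]
    assert x == pytest.approx(19.5, abs=0.1)
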