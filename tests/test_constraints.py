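"""Face maps, hard-constraint layers, normalization, and engine consistency."""

import numpy as np
import pytest

from needlepath import PlanConfig, generate_phantom
from needlepath.anatomy import tumor_centroid
from needlepath.constraints import (
    PlannerContext,
    ScalarChecker,
    build_face_maps,
    evaluate_hard,
    evaluate_soft,
    h2_passes,
    h3_passes,
    integrate_hard,
    normalize_s1,
    normalize_s2,
    normalize_s3,
)
from needlepath.errors import GeometryError
from needlepath.grid import boundary_cell_count, enumerate_boundary_cells
from needlepath.phantom import LABELS
from conftest import small_spec


class TestBoundaryEnumeration:
    def test_counting_formula_small_cube(self):
        assert boundary_cell_count((4, 4, 4)) == 56
        assert len(enumerate_boundary_cells((4, 4, 4))) == 56

    def test_counting_formula_ct_sized(self):
        w, h, d = 512, 512, 300
        assert boundary_cell_count((w, h, d)) == w * h * d - (w - 2) * (h - 2) * (d - 2)

    @pytest.mark.parametrize("shape", [(3, 5, 4), (7, 3, 9), (6, 6, 6)])
    def test_enumeration_is_a_bijection_onto_the_shell(self, shape):
        cells = enumerate_boundary_cells(shape)
        seen = np.zeros(shape, dtype=int)
        np.add.at(seen, tuple(cells.ijk.T), 1)
        shell = np.zeros(shape, dtype=bool)
        shell[[0, -1], :, :] = True
        shell[:, [0, -1], :] = True
        shell[:, :, [0, -1]] = True
        assert (seen[shell] == 1).all()
        assert (seen[~shell] == 0).all()

    def test_symmetric_cube_faces_congruent(self, small_scene):
        C = small_scene.origin + (np.asarray(small_scene.shape) - 1) * small_scene.spacing / 2
        fm = build_face_maps(small_scene, C)
        from needlepath.grid import FACES

        counts = [(fm.cells.face_id == i).sum() for i in range(6)]
        assert counts[0] == counts[1] and counts[2] == counts[3] and counts[4] == counts[5]

    def test_target_outside_box_rejected(self, small_scene):
        with pytest.raises(GeometryError):
            build_face_maps(small_scene, np.array([-10.0, 0.0, 0.0]))


class TestNormalization:
    def test_s1_endpoints_and_midpoint(self):
        feas = np.array([True, True, True])
        r, ext = normalize_s1(np.array([2.0, 5.0, 8.0]), feas)
        np.testing.assert_allclose(r, [0.0, 0.5, 1.0])
        assert ext == {"d_min": 2.0, "d_max": 8.0}

    def test_s2_shorter_is_better(self):
        feas = np.array([True, True, True])
        l, _ = normalize_s2(np.array([60.0, 80.0, 100.0]), feas)
        np.testing.assert_allclose(l, [1.0, 0.5, 0.0])

    def test_s3_larger_angle_is_better(self):
        feas = np.array([True, True, True])
        a, _ = normalize_s3(np.array([30.0, 60.0, 90.0]), feas)
        np.testing.assert_allclose(a, [0.0, 0.5, 1.0])

    def test_s3_printed_form_inverts(self):
        feas = np.array([True, True, True])
        a, _ = normalize_s3(np.array([30.0, 60.0, 90.0]), feas, printed_form=True)
        np.testing.assert_allclose(a, [1.0, 0.5, 0.0])

    def test_degenerate_range_scores_one(self):
        feas = np.array([True, True])
        r, _ = normalize_s1(np.array([4.0, 4.0]), feas)
        np.testing.assert_allclose(r, [1.0, 1.0])

    def test_infeasible_cells_carry_no_score(self):
        feas = np.array([True, False, True])
        r, _ = normalize_s1(np.array([2.0, 99.0, 8.0]), feas)
        assert np.isnan(r[1]) and r[0] == 0.0 and r[2] == 1.0


class TestStrictBoundaries:
    def test_h2_equality_fails(self):
        assert not h2_passes(100.0, 100.0)
        assert h2_passes(99.9, 100.0)

    def test_h3_equality_fails(self):
        assert not h3_passes(20.0, 20.0)
        assert h3_passes(20.0 + 1e-9, 20.0)

    def test_engine_h2_boundary_end_to_end(self, small_scene):
        # pick a feasible cell, set the needle length to its exact l: it must fail
        C = tumor_centroid(small_scene)
        fm = build_face_maps(small_scene, C)
        ctx = PlannerContext(small_scene, PlanConfig())
        evaluate_hard(ctx, fm)
        cell = int(np.flatnonzero(fm.feasible)[0])
        exact = float(fm.l[cell])
        cfg2 = PlanConfig(needle_length_mm=exact)
        fm2 = build_face_maps(small_scene, C)
        evaluate_hard(PlannerContext(small_scene, cfg2), fm2)
        assert fm2.h2[cell]
        assert not fm2.feasible[cell]


class TestIntegration:
    def test_or_integration_matches_boolean_oracle(self, small_scene, rng):
        C = tumor_centroid(small_scene)
        fm = build_face_maps(small_scene, C)
        n = len(fm)
        fm.h1, fm.h2, fm.h3, fm.h4 = (rng.random(n) < 0.3 for _ in range(4))
        feas = integrate_hard(fm)
        np.testing.assert_array_equal(feas, ~(fm.h1 | fm.h2 | fm.h3 | fm.h4))

    def test_all_pass_all_feasible(self, small_scene):
        C = tumor_centroid(small_scene)
        fm = build_face_maps(small_scene, C)
        n = len(fm)
        fm.h1 = fm.h2 = fm.h3 = fm.h4 = np.zeros(n, dtype=bool)
        assert integrate_hard(fm).all()

    def test_counts_partition_the_cells(self, small_plan):
        counts = small_plan["fm"].counts
        assert counts["feasible"] <= counts["cells"]
        union = (
            small_plan["fm"].h1 | small_plan["fm"].h2 | small_plan["fm"].h3 | small_plan["fm"].h4
        )
        assert counts["feasible"] + int(union.sum()) == counts["cells"]


class TestEngineAgainstScalarChecker:
    """The vectorized planner and the independent per-path checker agree."""

    def test_flags_and_raw_values_agree_on_sampled_cells(self, small_scene, rng):
        config = PlanConfig()
        C = tumor_centroid(small_scene)
        fm = build_face_maps(small_scene, C)
        ctx = PlannerContext(small_scene, config)
        evaluate_hard(ctx, fm)
        checker = ScalarChecker(small_scene, config)
        idx = rng.choice(len(fm), size=60, replace=False)
        for cell in idx:
            res = checker.check_all(fm.points[cell], C)
            assert res["pass"] == bool(fm.feasible[cell]), f"cell {cell}"
            if res["pass"]:
                assert res["l"] == pytest.approx(float(fm.l[cell]), abs=0.5)
                assert res["alpha"] == pytest.approx(float(fm.alpha[cell]), abs=2.0)


class TestH4:
    def test_deep_tumor_yields_empty_mask(self):
        spec = small_spec(tumor_center=(178.0, 112.0, 130.0), tumor_radius=10.0)
        scene = generate_phantom(spec)
        ctx = PlannerContext(scene, PlanConfig())
        assert ctx.h4_occ is None  # ablation zone + depth margin stays in the lung

    def test_subpleural_tumor_blocks_shallow_entries(self):
        # tumor close to the lateral pleura: the margin shell pokes out
        spec = small_spec(tumor_center=(196.0, 112.0, 130.0), tumor_radius=10.0)
        scene = generate_phantom(spec)
        config = PlanConfig()
        ctx = PlannerContext(scene, config)
        assert ctx.h4_occ is not None
        C = tumor_centroid(scene)
        fm = build_face_maps(scene, C)
        evaluate_hard(ctx, fm)
        assert fm.h4.any()
        # H4 failures only on cells whose rays cross the shell; shrinking the
        # margins back removes them
        tiny = PlanConfig(ablation_margin_mm=1.0, depth_margin_mm=1.0)
        fm2 = build_face_maps(scene, C)
        evaluate_hard(PlannerContext(scene, tiny), fm2)
        assert fm2.h4.sum() < fm.h4.sum()

    def test_margins_inside_lung_add_no_failures(self):
        spec = small_spec(tumor_center=(178.0, 112.0, 130.0), tumor_radius=10.0)
        scene = generate_phantom(spec)
        C = tumor_centroid(scene)
        fm = build_face_maps(scene, C)
        evaluate_hard(PlannerContext(scene, PlanConfig()), fm)
        assert not fm.h4.any()


class TestMonotonicity:
    def test_adding_risk_voxels_never_gains_feasibility(self, rng):
        spec = small_spec()
        scene = generate_phantom(spec)
        config = PlanConfig()
        C = tumor_centroid(scene)
        fm = build_face_maps(scene, C)
        evaluate_hard(PlannerContext(scene, config), fm)
        base = fm.feasible.copy()
        body = np.argwhere(scene.labels == LABELS["body"])
        for _ in range(20):
            labels2 = scene.labels.copy()
            pick = body[rng.choice(len(body), size=40, replace=False)]
            labels2[tuple(pick.T)] = LABELS["bone"]
            scene2 = generate_phantom(spec)  # fresh scene, then inject voxels
            scene2.volume.labels = labels2
            scene2._mask_cache.clear()
            fm2 = build_face_maps(scene2, C)
            evaluate_hard(PlannerContext(scene2, config), fm2)
            assert not (fm2.feasible & ~base).any()


class TestMirrorSymmetry:
    def test_feasibility_maps_mirror_with_the_tumor(self):
        spec = small_spec()
        cx = spec.volume_center[0]
        m_spec = spec.model_copy(
            update={"tumor_center": (2 * cx - spec.tumor_center[0], *spec.tumor_center[1:])}
        )
        config = PlanConfig()

        def feasibility(sp):
            scene = generate_phantom(sp)
            C = tumor_centroid(scene)
            fm = build_face_maps(scene, C)
            evaluate_hard(PlannerContext(scene, config), fm)
            return fm

        fm_a = feasibility(spec)
        fm_b = feasibility(m_spec)
        # mirror cell lookup: (i, j, k) -> (W-1-i, j, k)
        W = spec.shape[0]
        key = lambda ijk: (ijk[:, 0].astype(np.int64) * 10**8 + ijk[:, 1] * 10**4 + ijk[:, 2])
        order_a = np.argsort(key(fm_a.cells.ijk))
        mirrored = fm_b.cells.ijk.copy()
        mirrored[:, 0] = W - 1 - mirrored[:, 0]
        order_b = np.argsort(key(mirrored))
        fa = fm_a.feasible[order_a]
        fb = fm_b.feasible[order_b]
        disagree = fa != fb
        # allow a one-cell band at feasibility boundaries: every disagreement
        # must have both feasible and infeasible cells among its 3x3 face
        # neighborhood in run A
        from scipy import ndimage
        from needlepath.grid import FACES

        bad = 0
        ijk_sorted = fm_a.cells.ijk[order_a]
        fid_sorted = fm_a.cells.face_id[order_a]
        uv_sorted = fm_a.cells.uv[order_a]
        for face_idx, face in enumerate(FACES):
            sel_flat = fid_sorted == face_idx
            if not disagree[sel_flat].any():
                continue
            grid = fm_a.face_grid(face, fm_a.feasible.astype(float), fill=np.nan)
            edge = np.zeros(grid.shape, dtype=bool)
            known = ~np.isnan(grid)
            interior = grid == 1
            dil = ndimage.binary_dilation(interior, iterations=1)
            ero = ndimage.binary_erosion(interior, iterations=1)
            edge = dil & ~ero  # one-cell band around the feasibility boundary
            for u, v in uv_sorted[sel_flat & disagree]:
                if not edge[u, v]:
                    bad += 1
        assert bad == 0


def test_s1_full_ray_never_exceeds_percutaneous_minimum(small_scene):
    C = tumor_centroid(small_scene)
    cfg_p = PlanConfig()
    cfg_f = PlanConfig(s1_full_ray=True)
    fm_p = build_face_maps(small_scene, C)
    ctx = PlannerContext(small_scene, cfg_p)
    evaluate_hard(ctx, fm_p)
    evaluate_soft(ctx, fm_p)
    fm_f = build_face_maps(small_scene, C)
    ctx_f = PlannerContext(small_scene, cfg_f)
    evaluate_hard(ctx_f, fm_f)
    evaluate_soft(ctx_f, fm_f)
    feas = fm_p.feasible & fm_f.feasible
    assert np.all(fm_f.d[feas] <= fm_p.d[feas] + 1e-6)
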