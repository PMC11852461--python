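"""Pupil extraction: binarization, tracing, fitting, constraint screening."""

import numpy as np
import pytest
from skimage.draw import disk

from oculoscreen.exceptions import FitFailureError, NoPupilFoundError, UntraceableError
from oculoscreen.geometry import PupilEllipse
from oculoscreen.pupil import (
    BoundaryChain,
    PupilConfig,
    binarize_pupil,
    constraint_convexity,
    constraint_curvature,
    constraint_extent,
    extract_boundary,
    extract_pupil,
    extract_pupil_sequence,
    fit_ellipse_lsq,
    preprocess,
    refine_and_refit,
    screen_boundary_points,
)
from oculoscreen.simulator import render_eye_frame, sample_scene


def ellipse_points(a, b, n=36, center=(0.0, 0.0), tilt=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ct, st = np.cos(tilt), np.sin(tilt)
    return np.stack([center[0] + x * ct - y * st, center[1] + x * st + y * ct], axis=1)


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        assert np.array_equal(preprocess(img), img)

    def test_impulse_noise_attenuated(self, clean_disc_frame, clean_disc_scene, rng):
        clean = render_eye_frame(clean_disc_scene, seed=0).image.astype(float)
        noisy = clean.copy()
        ys = rng.integers(0, clean.shape[0], 200)
        xs = rng.integers(0, clean.shape[1], 200)
        noisy[ys, xs] = 255
        dev_before = np.abs(noisy - clean).max()
        dev_after = np.abs(preprocess(noisy) - clean).max()
        assert dev_after < dev_before

    def test_shape_and_dtype_preserved(self, clean_disc_frame):
        out = preprocess(clean_disc_frame)
        assert out.image.shape == clean_disc_frame.image.shape
        assert out.image.dtype == clean_disc_frame.image.dtype


class TestBinarize:
    def test_noiseless_disc_mask_matches_disc(self, clean_disc_frame, clean_disc_scene):
        mask = binarize_pupil(clean_disc_frame)
        h, w = mask.shape
        truth = np.zeros((h, w), bool)
        rr, cc = disk(clean_disc_scene.pupil_ellipse.center[::-1], 30, shape=(h, w))
        truth[rr, cc] = True
        from scipy.ndimage import binary_dilation

        assert not (mask & ~binary_dilation(truth, iterations=1)).any()
        assert not (truth & ~binary_dilation(mask, iterations=1)).any()

    def test_boundary_glint_dents_the_mask(self, clean_disc_scene):
        import dataclasses

        pe = clean_disc_scene.pupil_ellipse
        glint_center = tuple(pe.point_at(0.0))
        scene = dataclasses.replace(
            clean_disc_scene, glint_centers=[glint_center], glint_radius=8.0
        )
        mask = binarize_pupil(render_eye_frame(scene, seed=0).image)
        gx, gy = int(round(glint_center[0])), int(round(glint_center[1]))
        # pixels just inside the pupil at the glint are carved out
        assert not mask[gy, gx - 3]
        # while the opposite side of the boundary is intact
        ox, oy = pe.point_at(np.pi)
        assert mask[int(round(oy)), int(round(ox)) + 3]

    def test_featureless_bright_image_rejected(self):
        with pytest.raises(NoPupilFoundError):
            binarize_pupil(np.full((100, 100), 255, dtype=np.uint8))


class TestBoundaryTracing:
    def test_filled_square_contour_has_4s_minus_4_points(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # 10x10 square
        chain = extract_boundary(mask)
        assert len(chain) == 36

    def test_disc_contour_points_at_radius(self):
        mask = np.zeros((100, 100), bool)
        rr, cc = disk((50, 50), 30)
        mask[rr, cc] = True
        chain = extract_boundary(mask)
        d = np.hypot(chain.points[:, 0] - 50, chain.points[:, 1] - 50)
        assert np.all((d > 30 - 1.5) & (d < 30 + 1.5))

    def test_chain_is_closed(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 12:22] = True
        chain = extract_boundary(mask)
        gap = np.abs(chain.points[0] - chain.points[-1]).max()
        assert gap <= 1  # 8-connected neighbors

    def test_component_spanning_all_borders_rejected(self):
        mask = np.ones((50, 50), bool)
        with pytest.raises(UntraceableError):
            extract_boundary(mask)


class TestEllipseFit:
    def test_exact_points_recovered(self):
        pts = ellipse_points(5, 3, n=12)
        e = fit_ellipse_lsq(pts)
        assert e.center == pytest.approx((0, 0), abs=1e-6)
        assert (e.a, e.b) == pytest.approx((5, 3), abs=1e-6)

    def test_small_perturbation_small_center_shift(self):
        pts = ellipse_points(5, 3, n=12)
        pts[:, 0] += 0.01
        e = fit_ellipse_lsq(pts)
        assert np.hypot(*e.center) < 0.05

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5), np.arange(5) * 2.0], axis=1)
        with pytest.raises(FitFailureError):
            fit_ellipse_lsq(pts)

    def test_axes_ordered_and_tilt_normalized(self):
        pts = ellipse_points(3, 7, n=24, tilt=0.3)
        e = fit_ellipse_lsq(pts)
        assert e.a >= e.b > 0
        assert 0 <= e.tilt < np.pi


class TestConstraints:
    def test_perpendicular_tangent_accepted(self):
        assert constraint_curvature((10, 0), (9.8, -2), (9.8, 2), (0, 0))

    def test_radial_spike_rejected(self):
        assert not constraint_curvature((10, 0), (8, 0), (12, 0), (0, 0))

    def test_curvature_passes_entire_discretized_circle(self, unit_circle_360):
        pts = unit_circle_360
        n = len(pts)
        for i in range(n):
            assert constraint_curvature(pts[i], pts[i - 1], pts[(i + 1) % n], (0, 0))

    def test_convexity_passes_entire_discretized_circle(self, unit_circle_360):
        pts = unit_circle_360
        n = len(pts)
        for i in range(n):
            assert constraint_convexity(pts[i], pts[i - 1], pts[(i + 1) % n], (0, 0))

    def test_outward_dent_rejected_by_convexity(self):
        # point pulled inside the arc: second difference points outward
        assert not constraint_convexity((25, 0), (29.5, -5), (29.5, 5), (0, 0))

    def test_collinear_triple_rejected_by_convexity(self):
        assert not constraint_convexity((1, 1), (0, 0), (2, 2), (5, -5))

    def test_extent_band_interior_and_exterior(self):
        coarse = PupilEllipse((0, 0), 20, 10, 0)
        assert constraint_extent((15, 0), coarse)
        assert not constraint_extent((24, 0), coarse, delta_hi=3)

    def test_extent_on_circle_needs_lower_slack(self, unit_circle_360):
        coarse = PupilEllipse((0, 0), 30, 30, 0)
        assert all(constraint_extent(p, coarse, delta_lo=1.5) for p in unit_circle_360)
        # with a hard lower bound b the strict inequality rejects on-circle
        # points (up to floating-point jitter around the exact radius)
        passed = [constraint_extent(p, coarse, delta_lo=0.0) for p in unit_circle_360]
        assert not all(passed)


class TestRefinement:
    def test_pure_ellipse_unchanged_and_few_points_removed(self):
        pts = ellipse_points(30, 24, n=240, center=(50, 40), tilt=0.4)
        chain = BoundaryChain(pts)
        coarse = fit_ellipse_lsq(chain)
        keep = screen_boundary_points(chain, coarse, PupilConfig(neighbor_stride=1))
        assert keep.mean() > 0.95
        refined, flags = refine_and_refit(chain, coarse, PupilConfig(neighbor_stride=1))
        shift = np.hypot(
            refined.center[0] - coarse.center[0], refined.center[1] - coarse.center[1]
        )
        assert shift < 0.1 and not flags

    def test_glint_distortion_removed_improves_center(self, glinted_scene):
        # a boundary-straddling glint carves a concave dent into the traced
        # chain; screening the dent out must bring the refit center closer
        # to the true pupil center than the coarse fit
        res = extract_pupil(render_eye_frame(glinted_scene, seed=3))
        assert res.ok and "refinement-degraded" not in res.flags
        tx, ty = glinted_scene.pupil_ellipse.center
        err_coarse = np.hypot(res.coarse.center[0] - tx, res.coarse.center[1] - ty)
        err_refined = np.hypot(res.ellipse.center[0] - tx, res.ellipse.center[1] - ty)
        assert err_refined < err_coarse
        assert err_refined < 1.0

    def test_all_points_failing_falls_back_to_coarse(self):
        pts = ellipse_points(30, 28, n=100, center=(50, 40))
        chain = BoundaryChain(pts)
        coarse = fit_ellipse_lsq(chain)
        # absurd extent band rejects everything
        cfg = PupilConfig(delta_hi=-40, delta_lo=-40)
        refined, flags = refine_and_refit(chain, coarse, cfg)
        assert refined is coarse
        assert "refinement-degraded" in flags

    def test_survivors_never_exceed_chain_length(self, glinted_scene):
        res = extract_pupil(render_eye_frame(glinted_scene, seed=1))
        assert 0 < res.n_survivors <= res.n_boundary


class TestFullPipeline:
    def test_clean_frame_center_within_one_pixel(self, clean_disc_scene, clean_disc_frame):
        res = extract_pupil(clean_disc_frame)
        assert res.ok
        tx, ty = clean_disc_scene.pupil_ellipse.center
        assert np.hypot(res.ellipse.center[0] - tx, res.ellipse.center[1] - ty) < 1.0

    def test_glinted_frame_refinement_not_worse_than_coarse(self, rng):
        worse = 0
        for i in range(10):
            scene = sample_scene(rng)
            res = extract_pupil(render_eye_frame(scene, seed=i))
            assert res.ok
            tx, ty = scene.pupil_ellipse.center
            e_ref = np.hypot(res.ellipse.center[0] - tx, res.ellipse.center[1] - ty)
            e_coa = np.hypot(res.coarse.center[0] - tx, res.coarse.center[1] - ty)
            worse += e_ref > e_coa + 0.1
        assert worse <= 2

    def test_fully_occluded_frame_flagged_not_raised(self):
        skin = np.full((240, 320), 120, dtype=np.uint8)
        res = extract_pupil(skin)
        assert not res.ok
        assert "no-pupil" in res.flags

    def test_sequence_blink_flagging(self, clean_disc_scene, clean_disc_frame):
        frames = [clean_disc_frame] * 6
        skin = np.full_like(clean_disc_frame.image, 120)
        # a near-empty frame after healthy ones should be blink-suspect or missing
        frames = frames + [skin]
        results = extract_pupil_sequence(frames)
        assert all(r.ok for r in results[:6])
        assert (not results[6].ok) or ("blink-suspect" in results[6].flags)
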