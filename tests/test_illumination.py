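"""Mask geometry: point validation, line clipping, border profiles, the
stepwise mask build, and mask application."""

import numpy as np
import pytest

import koehler
from koehler import illumination as il
from koehler.errors import (
    ColinearPointsError,
    DuplicatePointError,
    NoWhiteAreaError,
    OutOfBoundsError,
    ValidationError,
)

from oracles import brute_force_mask, random_point_set


def pset(coords_l, reference=100.0):
    return il.SourcePointSet(
        tuple(il.SourcePoint(float(x), float(y), float(l)) for x, y, l in coords_l),
        reference=reference,
    )


def plane_pset(alpha, beta, coords, reference=100.0):
    """Points whose L* is sampled from L = reference − αx − βy."""
    return pset(
        [(x, y, reference - alpha * x - beta * y) for x, y in coords],
        reference=reference,
    )


class TestValidatePoints:
    def test_image_corners_are_valid(self):
        pts = pset([(0, 0, 95), (9, 0, 96), (0, 9, 97), (9, 9, 98)])
        assert il.validate_points(pts, (10, 10)) is pts

    def test_three_on_a_row_are_colinear(self):
        pts = pset([(1, 2, 95), (4, 2, 96), (7, 2, 97), (5, 8, 98)])
        with pytest.raises(ColinearPointsError):
            il.validate_points(pts, (10, 10))

    def test_out_of_bounds_point(self):
        pts = pset([(-1, 0, 95), (9, 0, 96), (0, 9, 97), (9, 9, 98)])
        with pytest.raises(OutOfBoundsError):
            il.validate_points(pts, (10, 10))

    def test_duplicate_point(self):
        pts = pset([(3, 3, 95), (3, 3, 96), (0, 9, 97), (9, 0, 98)])
        with pytest.raises(DuplicatePointError):
            il.validate_points(pts, (10, 10))

    def test_wrong_count_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            il.SourcePointSet((il.SourcePoint(0, 0, 95),))


class TestLineRectangleIntersections:
    def test_horizontal_line_exits_left_and_right(self):
        a, b = il.line_rectangle_intersections((3, 5), (7, 5), (10, 10))
        assert {a, b} == {(0.0, 5.0), (9.0, 5.0)}

    def test_same_border_points_map_to_themselves(self):
        a, b = il.line_rectangle_intersections((0, 2), (0, 8), (10, 10))
        assert {a, b} == {(0.0, 2.0), (0.0, 8.0)}

    def test_main_diagonal_hits_opposite_corners(self):
        a, b = il.line_rectangle_intersections((2, 2), (4, 4), (10, 10))
        assert {a, b} == {(0.0, 0.0), (9.0, 9.0)}

    def test_identical_points_are_degenerate(self):
        with pytest.raises(ValidationError):
            il.line_rectangle_intersections((3, 3), (3, 3), (10, 10))


class TestExtrapolation:
    def test_constant_deficit_stays_zero(self):
        p, q = il.SourcePoint(2, 2, 100), il.SourcePoint(6, 6, 100)
        assert il.extrapolate_mask_to_boundary(p, q, (9.0, 9.0)) == pytest.approx(0.0)

    def test_arithmetic_extrapolation_beyond_q(self):
        # deficits 2 at t=0 and 4 at t=1 extrapolate to 6 at t=2
        p, q = il.SourcePoint(0, 0, 98), il.SourcePoint(1, 0, 96)
        assert il.extrapolate_mask_to_boundary(p, q, (2.0, 0.0)) == pytest.approx(6.0)

    def test_matches_plane_along_any_line(self, rng):
        alpha, beta = 0.05, 0.1
        for _ in range(20):
            (x1, y1), (x2, y2) = rng.uniform(0, 15, (2, 2))
            if np.hypot(x2 - x1, y2 - y1) < 1e-3:
                continue
            p = il.SourcePoint(x1, y1, 100 - alpha * x1 - beta * y1)
            q = il.SourcePoint(x2, y2, 100 - alpha * x2 - beta * y2)
            bx = x1 + 3.7 * (x2 - x1)
            by = y1 + 3.7 * (y2 - y1)
            got = il.extrapolate_mask_to_boundary(p, q, (bx, by))
            assert got == pytest.approx(alpha * bx + beta * by, abs=1e-9)


class TestBorderProfiles:
    def test_equal_values_give_constant_profile(self):
        prof = il.border_profiles(
            {"top": [(1.0, 3.0), (7.0, 3.0)], "bottom": [(0.0, 3.0), (9.0, 3.0)],
             "left": [(0.0, 3.0), (9.0, 3.0)], "right": [(0.0, 3.0), (9.0, 3.0)]},
            (10, 10),
        )
        for vals in prof.values():
            assert np.allclose(vals, 3.0)

    def test_single_pair_extrapolates_linearly(self):
        prof = il.border_profiles(
            {"top": [(2.0, 1.0), (6.0, 3.0)], "bottom": [(0.0, 0.0), (9.0, 1.0)],
             "left": [(0.0, 0.0), (9.0, 1.0)], "right": [(0.0, 0.0), (9.0, 1.0)]},
            (10, 10),
        )
        assert prof["top"][0] == pytest.approx(0.0)
        assert prof["top"][9] == pytest.approx(4.5)

    def test_sparse_border_falls_back_to_plane_fit(self):
        alpha, beta = 0.2, 0.1
        pts = plane_pset(alpha, beta, [(2, 3), (7, 2), (3, 8), (8, 7)])
        prof = il.border_profiles(
            {"top": [], "bottom": [], "left": [], "right": []}, (10, 10), pts
        )
        x = np.arange(10.0)
        assert np.allclose(prof["top"], alpha * x, atol=1e-9)
        assert np.allclose(prof["bottom"], alpha * x + beta * 9, atol=1e-9)
        assert np.allclose(prof["left"], beta * x, atol=1e-9)
        assert np.allclose(prof["right"], alpha * 9 + beta * x, atol=1e-9)


class TestBuildMask:
    def test_zero_deficit_gives_zero_mask(self):
        pts = pset([(1, 1, 100), (8, 1, 100), (1, 8, 100), (8, 8, 100)])
        assert np.allclose(il.build_mask(pts, (10, 10)), 0.0, atol=1e-12)

    def test_exact_on_planar_field(self):
        alpha, beta = 0.05, 0.1
        pts = plane_pset(alpha, beta, [(1, 1), (8, 1), (1, 8), (8, 8)])
        mask = il.build_mask(pts, (32, 32))
        xx, yy = np.meshgrid(np.arange(32.0), np.arange(32.0))
        assert np.abs(mask - (alpha * xx + beta * yy)).max() < 1e-6

    def test_reproduces_source_deficits_for_planar_sets(self, rng):
        # the stepwise geometry interpolates its anchors exactly on the
        # planar family it was designed for
        for _ in range(20):
            alpha, beta = rng.uniform(-0.2, 0.2, 2)
            coords = [(2, 3), (12, 2), (3, 11), (13, 12)]
            pts = plane_pset(alpha, beta, coords)
            mask = il.build_mask(pts, (16, 16))
            for p in pts.points:
                assert mask[int(p.y), int(p.x)] == pytest.approx(
                    100.0 - p.lstar, abs=1e-6
                )

    def test_spec_example_matches_plane_and_oracle(self):
        pts = pset([(1, 1, 96), (8, 1, 94), (1, 8, 90), (8, 8, 88)])
        mask = il.build_mask(pts, (10, 10))
        # these deficits happen to lie on the plane 4 + (2/7)(x-1) + (6/7)(y-1)
        assert mask[4, 4] == pytest.approx(4 + 24 / 7, abs=1e-9)
        oracle = brute_force_mask([(p.x, p.y, p.lstar) for p in pts.points], 10, 10)
        assert np.abs(mask - oracle).max() < 1e-9

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(30):
            triple = random_point_set(rng, 16, 16)
            pts = pset(triple)
            mask = il.build_mask(pts, (16, 16))
            oracle = brute_force_mask(triple, 16, 16)
            assert np.abs(mask - oracle).max() < 1e-9


class TestApplyCorrection:
    def _lab(self, rng, h=12, w=12):
        lab = np.zeros((h, w, 3))
        lab[..., 0] = rng.uniform(20, 95, (h, w))
        lab[..., 1] = rng.uniform(-30, 30, (h, w))
        lab[..., 2] = rng.uniform(-30, 30, (h, w))
        return lab

    def test_zero_mask_is_identity(self, rng):
        lab = self._lab(rng)
        out = il.apply_correction(lab, np.zeros((12, 12)))
        assert np.array_equal(out, lab)

    def test_factor_five_restores_reference_at_source_points(self):
        pts = plane_pset(0.1, 0.2, [(1, 1), (8, 2), (2, 8), (9, 9)])
        mask = il.build_mask(pts, (12, 12))
        lab = np.zeros((12, 12, 3))
        for p in pts.points:
            lab[int(p.y), int(p.x), 0] = p.lstar
        out = il.apply_correction(lab, mask, il.CorrectionSettings(factor=5))
        for p in pts.points:
            assert out[int(p.y), int(p.x), 0] == pytest.approx(100.0, abs=1e-6)

    def test_output_nondecreasing_in_factor(self, rng):
        lab = self._lab(rng)
        mask = rng.uniform(0, 10, (12, 12))
        prev = il.apply_correction(lab, mask, il.CorrectionSettings(factor=1))
        for f in range(2, 6):
            cur = il.apply_correction(lab, mask, il.CorrectionSettings(factor=f))
            assert np.all(cur[..., 0] >= prev[..., 0] - 1e-12)
            prev = cur

    def test_chromaticity_bitwise_unchanged(self, rng):
        lab = self._lab(rng)
        out = il.apply_correction(lab, rng.uniform(-5, 10, (12, 12)))
        assert np.array_equal(out[..., 1], lab[..., 1])
        assert np.array_equal(out[..., 2], lab[..., 2])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            il.apply_correction(self._lab(rng), np.zeros((5, 5)))

    def test_factor_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            il.CorrectionSettings(factor=6)
        with pytest.raises(ValidationError):
            il.CorrectionSettings(factor=0)


class TestAutoSelectPoints:
    @staticmethod
    def _flat_lab(h, w, L=60.0):
        lab = np.zeros((h, w, 3))
        lab[..., 0] = L
        return lab

    def test_singleton_candidates_are_selected_exactly(self):
        lab = self._flat_lab(20, 20)
        spots = [(3, 4, 95.0), (15, 5, 93.0), (4, 14, 91.0), (16, 16, 97.0)]
        for x, y, l in spots:
            lab[y, x, 0] = l
        pts = il.auto_select_points(lab)
        got = {(p.x, p.y, p.lstar) for p in pts.points}
        assert got == {(float(x), float(y), l) for x, y, l in spots}

    def test_empty_quadrant_uses_mirrored_centroid_and_mean_deficit(self):
        lab = self._flat_lab(20, 20)
        spots = [(3, 4, 95.0), (15, 5, 93.0), (4, 14, 91.0)]  # BR quadrant empty
        for x, y, l in spots:
            lab[y, x, 0] = l
        pts = il.auto_select_points(lab)
        synth = [p for p in pts.points if (p.x, p.y) not in {(3, 4), (15, 5), (4, 14)}]
        assert len(synth) == 1
        # mirrors into BR: (3,4)->(16,15), (15,5)->(15,14), (4,14)->(15,14)
        assert (synth[0].x, synth[0].y) == (15.0, 14.0)
        assert synth[0].lstar == pytest.approx(100.0 - np.mean([5.0, 7.0, 9.0]))

    def test_no_white_pixel_raises(self):
        with pytest.raises(NoWhiteAreaError):
            il.auto_select_points(self._flat_lab(10, 10))

    def test_uniform_white_image_yields_zero_mask(self):
        lab = self._flat_lab(16, 16, L=100.0)
        pts = il.auto_select_points(lab)
        mask = il.build_mask(pts, (16, 16))
        assert np.allclose(mask, 0.0, atol=1e-9)

    def test_centroid_nearest_candidate_in_crowded_quadrant(self):
        lab = self._flat_lab(20, 20)
        # TL quadrant candidates forming a cluster: centroid near (4, 4)
        for x, y in [(2, 2), (6, 2), (2, 6), (6, 6), (4, 4)]:
            lab[y, x, 0] = 96.0
        for x, y in [(15, 3), (3, 15), (15, 15)]:
            lab[y, x, 0] = 96.0
        pts = il.auto_select_points(lab)
        assert any((p.x, p.y) == (4.0, 4.0) for p in pts.points)


class TestEndToEndRecovery:
    def test_planar_degradation_recovered_via_auto_points(self):
        ph = koehler.generate_phantom(height=128, width=128, n_nuclei=8, seed=11)
        corrected, mask, _ = koehler.correct_rgb(ph.degraded)
        from koehler.imgio import from_uint8, to_uint8

        report = koehler.measure_recovery(ph, from_uint8(to_uint8(corrected)))
        assert report.white_rmse < 0.5
        assert report.overall_rmse < 1.0
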