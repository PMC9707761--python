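"""Geometric feature values, documented ranges, and rigid-motion
invariance."""

import math

import numpy as np
import pytest

from ehgm.features import (
    LabeledPosture,
    axial_twist_angle,
    lateral_axial_twist_angle,
    lateral_pair_distance,
    midpoint_bend_angle,
    midpoint_distance,
    pair_distance_ratio,
    pair_frame,
    planar_intersection_angle,
    posture_sum_features,
    side_chord_length,
    side_cosine_similarity,
)


def rigid_motion(rng):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return lambda p: R @ np.asarray(p, float) + t


def random_pair(rng, spread=10.0):
    return (rng.uniform(-spread, spread, 3), rng.uniform(-spread, spread, 3))


class TestDistances:
    def test_345_triangle(self):
        assert lateral_pair_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_symmetric_and_zero(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 6, 3])
        assert lateral_pair_distance(a, b) == lateral_pair_distance(b, a)
        assert lateral_pair_distance(a, a) == 0.0

    def test_matches_sum_of_squares_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            ref = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert side_chord_length(a, b) == pytest.approx(ref, rel=1e-12)

    def test_chord_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c = (rng.normal(size=3) for _ in range(3))
            assert side_chord_length(a, c) <= (
                side_chord_length(a, b) + side_chord_length(b, c) + 1e-12
            )


class TestRatiosAndMidpoints:
    def test_equal_widths_unit_ratio(self):
        pi = ((0, 0, 0), (2, 0, 0))
        pj = ((0, 5, 0), (2, 5, 0))
        assert pair_distance_ratio(pi, pj) == pytest.approx(1.0)

    def test_ratio_two_and_reciprocal(self):
        pi = ((0, 0, 0), (2, 0, 0))
        pj = ((0, 5, 0), (1, 5, 0))
        assert pair_distance_ratio(pi, pj) == pytest.approx(2.0)
        assert pair_distance_ratio(pj, pi) == pytest.approx(0.5)

    def test_degenerate_denominator(self):
        pi = ((0, 0, 0), (1, 0, 0))
        pj = ((0, 5, 0), (1e-15, 5, 0))
        with pytest.raises(ValueError, match="degenerate pair"):
            pair_distance_ratio(pi, pj)

    def test_midpoint_distance_values(self):
        pi = ((0, 0, 0), (2, 0, 0))
        pj = ((1, 0, 0), (1, 2, 0))  # midpoint (1, 1, 0)
        assert midpoint_distance(pi, pi) == 0.0
        assert midpoint_distance(pi, pj) == pytest.approx(1.0)


class TestCosines:
    def test_parallel_antiparallel_orthogonal(self):
        pi = ((0, 0, 0), (1, 0, 0))
        parallel = ((0, 0, 2), (1, 0, 2))
        assert side_cosine_similarity(pi, parallel) == pytest.approx(1.0)
        anti = ((0, 0, 2), (-1, 0, 4))  # left chord +z, right chord points back
        pj = ((0.5, 0, 2), (0.5, 1, 0))
        # construct explicitly: left chord along +z, right chord along -z
        pi2 = ((0, 0, 0), (5, 0, 0))
        pj2 = ((0, 0, 2), (5, 0, -2))
        assert side_cosine_similarity(pi2, pj2) == pytest.approx(-1.0)
        pj3 = ((0, 0, 2), (5, 2, 0))
        assert side_cosine_similarity(pi2, pj3) == pytest.approx(0.0)


class TestTwistAngles:
    def chord_rotated_pair(self, theta):
        """pair_j's axis is pair_i's axis rotated by theta about the
        midpoint chord (+z)."""
        pi = ((-1, 0, 0), (1, 0, 0))
        c, s = math.cos(theta), math.sin(theta)
        axis = np.array([c, s, 0.0])  # +x rotated by theta about +z
        pj = (tuple(-axis + [0, 0, 4]), tuple(axis + [0, 0, 4]))
        return pi, pj

    def test_untwisted_zero(self):
        pi, pj = self.chord_rotated_pair(0.0)
        assert axial_twist_angle(pi, pj) == pytest.approx(0.0)

    def test_quarter_turn_ninety(self):
        pi, pj = self.chord_rotated_pair(math.pi / 2)
        assert axial_twist_angle(pi, pj) == pytest.approx(90.0)

    def test_sign_flips_under_reflection(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pi, pj = random_pair(rng), random_pair(rng)
            try:
                phi = axial_twist_angle(pi, pj)
            except ValueError:
                continue
            mirror = lambda p: np.asarray(p, float) * np.array([1.0, 1.0, -1.0])
            phi_m = axial_twist_angle(
                (mirror(pi[0]), mirror(pi[1])), (mirror(pj[0]), mirror(pj[1]))
            )
            assert phi_m == pytest.approx(-phi, abs=1e-9) or (
                abs(phi) == pytest.approx(180.0, abs=1e-9)
            )

    def test_lateral_twist_parallel_and_opposed(self):
        pi = ((-1, 0, 0), (1, 0, 0))
        pj_par = ((-1, 5, 0), (1, 5, 0))
        pj_opp = ((1, 5, 0), (-1, 5, 0))
        assert lateral_axial_twist_angle(pi, pj_par) == pytest.approx(0.0)
        assert lateral_axial_twist_angle(pi, pj_opp) == pytest.approx(180.0)


class TestBendAndPlanes:
    def make_pairs(self, mids):
        """Pairs with unit x-axis widths at the given midpoints."""
        off = np.array([0.5, 0.0, 0.0])
        return [
            (np.asarray(m, float) - off, np.asarray(m, float) + off) for m in mids
        ]

    @pytest.mark.parametrize(
        "mids,expected",
        [
            ([(0, 0, 0), (0, 1, 0), (0, 2, 0)], 180.0),  # collinear
            ([(0, 0, 0), (0, 1, 0), (0, 1, 1)], 90.0),
            ([(0, 0, 0), (0, 1, 0), (0, 0.5, math.sqrt(3) / 2)], 60.0),  # equilateral
        ],
    )
    def test_bend_angle_special_values(self, mids, expected):
        p = self.make_pairs(mids)
        assert midpoint_bend_angle(*p) == pytest.approx(expected, abs=1e-9)

    def test_coincident_midpoints_error(self):
        p = self.make_pairs([(0, 0, 0), (0, 0, 0.0), (0, 1, 0)])
        with pytest.raises(ValueError, match="midpoint"):
            midpoint_bend_angle(p[0], p[0], p[2])

    def test_coplanar_quads_zero_angle(self):
        p = self.make_pairs([(0, 0, 0), (0, 3, 0), (0, 6, 1)])
        # all nuclei have z in a common plane? construct truly coplanar:
        p = self.make_pairs([(0, 0, 0), (1, 3, 0), (0, 6, 0)])
        assert planar_intersection_angle(*p) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_quads(self):
        off = np.array([0.5, 0.0, 0.0])
        pi = ((-off), (+off))
        pj = (np.array([-0.5, 3, 0]), np.array([0.5, 3, 0]))
        # third pair offset along z so its quad spans the xz-ish plane
        pk = (np.array([-0.5, 3, 3]), np.array([0.5, 3, 3]))
        angle = planar_intersection_angle(pi, pj, pk)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_collinear_quad_errors(self):
        a = (np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        b = (np.array([2.0, 0, 0]), np.array([3.0, 0, 0]))
        c = (np.array([0.0, 1, 0]), np.array([1.0, 1, 0]))
        with pytest.raises(ValueError, match="rank-deficient"):
            planar_intersection_angle(a, b, c)


class TestRigidMotionInvariance:
    FEATURES = [
        (lateral_pair_distance, 2, "points"),
        (midpoint_distance, 2, "pairs"),
        (side_cosine_similarity, 2, "pairs"),
        (axial_twist_angle, 2, "pairs"),
        (lateral_axial_twist_angle, 2, "pairs"),
        (midpoint_bend_angle, 3, "pairs"),
        (planar_intersection_angle, 3, "pairs"),
    ]

    @pytest.mark.parametrize("fn,arity,kind", FEATURES)
    def test_invariant_under_rotation_translation(self, fn, arity, kind):
        rng = np.random.default_rng(hash((fn.__name__,)) % 2**31)
        for _ in range(10):
            move = rigid_motion(rng)
            if kind == "points":
                args = [rng.uniform(-10, 10, 3) for _ in range(arity)]
                moved = [move(a) for a in args]
            else:
                args = [random_pair(rng) for _ in range(arity)]
                moved = [(move(a), move(b)) for a, b in args]
            try:
                ref = fn(*args)
            except ValueError:
                continue
            assert fn(*moved) == pytest.approx(ref, abs=1e-7)

    def test_documented_ranges(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pi, pj, pk = (random_pair(rng) for _ in range(3))
            try:
                assert -1.0 <= side_cosine_similarity(pi, pj) <= 1.0
                assert -180.0 < axial_twist_angle(pi, pj) <= 180.0
                assert 0.0 <= lateral_axial_twist_angle(pi, pj) <= 180.0
                assert 0.0 <= midpoint_bend_angle(pi, pj, pk) <= 180.0
                assert 0.0 <= planar_intersection_angle(pi, pj, pk) <= 90.0
                assert lateral_pair_distance(*pi) >= 0.0
            except ValueError:
                continue


class TestPostureSums:
    def straight_worm_pairs(self, n=5, width=2.0, spacing=10.0):
        return [
            (np.array([-width / 2, 0, q * spacing]), np.array([width / 2, 0, q * spacing]))
            for q in range(n)
        ]

    def test_straight_untwisted_worm_identities(self):
        pairs = self.straight_worm_pairs()
        sums = posture_sum_features(pairs)
        assert sums["sum_axial_twist"] == pytest.approx(0.0, abs=1e-9)
        assert sums["sum_lateral_twist"] == pytest.approx(0.0, abs=1e-9)
        assert sums["sum_bend_angle"] == pytest.approx(180.0 * (5 - 2))
        assert sums["sum_pair_ratio"] == pytest.approx(5 - 1)  # equal widths

    def test_sums_equal_per_position_recomputation(self):
        rng = np.random.default_rng(12)
        pairs = [random_pair(rng) for _ in range(5)]
        from ehgm.features import (
            axial_twist_angle as phi,
            midpoint_bend_angle as bend,
        )
        sums = posture_sum_features(pairs)
        assert sums["sum_axial_twist"] == pytest.approx(
            sum(phi(pairs[q], pairs[q + 1]) for q in range(4)), rel=1e-12
        )
        assert sums["sum_bend_angle"] == pytest.approx(
            sum(bend(pairs[q], pairs[q + 1], pairs[q + 2]) for q in range(3)), rel=1e-12
        )


class TestLabeledPosture:
    def test_validates_name_order(self):
        left = np.zeros((3, 3)) + np.arange(3)[:, None]
        right = left + np.array([1.0, 0, 0])
        with pytest.raises(ValueError, match="anterior to posterior"):
            LabeledPosture(("T", "V6", "H0"), left, right, 0.0)

    def test_branch_order_reverses_pairs(self):
        left = np.arange(9, dtype=float).reshape(3, 3)
        right = left + np.array([1.0, 0, 0])
        p = LabeledPosture(("H0", "V3", "T"), left, right, 0.5)
        assert [n for n, _, _ in p.branch_pairs()] == ["T", "V3", "H0"]

    def test_pair_frame_unit_vectors(self):
        f = pair_frame(((0, 0, 0), (2, 0, 0)), ((0, 5, 0), (2, 5, 0)))
        assert np.linalg.norm(f.axis) == pytest.approx(1.0)
        assert np.linalg.norm(f.forward) == pytest.approx(1.0)
        assert f.axis @ np.array([1, 0, 0]) == pytest.approx(1.0)
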