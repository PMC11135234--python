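"""Tests for curve classification and unit-invariant knee detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uiknmf as u


def brute_force_knee(x, y):
    """Oracle: argmax over points of vertical distance to the endpoint chord."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best_i, best_d = 0, -1.0
    for i in range(len(x)):
        L = y[0] + (x[i] - x[0]) * (y[-1] - y[0]) / (x[-1] - x[0])
        d = abs(y[i] - L)
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    return x[best_i]


def random_convex_decreasing(rng, n):
    """Strictly convex decreasing curve: negative slopes increasing toward 0."""
    x = np.cumsum(rng.uniform(0.5, 2.0, n))
    gaps = np.sort(rng.uniform(0.1, 5.0, n - 1))[::-1]
    y = 100.0 - np.concatenate([[0.0], np.cumsum(gaps)])
    return x, y


class TestCheckCurve:
    @pytest.mark.parametrize(
        "fy,expected",
        [
            (lambda x: 1 / x, ("convex", "decreasing")),
            (lambda x: x**2, ("convex", "increasing")),
            (lambda x: np.sqrt(x), ("concave", "increasing")),
        ],
    )
    def test_known_shapes(self, fy, expected):
        x = np.arange(1.0, 7.0)
        ct = u.check_curve(u.Curve(x, fy(x)))
        assert (ct.convexity, ct.trend) == expected

    def test_constant_curve_rejected(self):
        with pytest.raises(u.DegenerateCurveError):
            u.check_curve(u.Curve([1, 2, 3, 4], [5, 5, 5, 5]))


class TestChordDistanceProfile:
    def test_worked_example(self):
        c = u.Curve([1, 2, 3, 4, 5], [10, 6, 3, 1.5, 1])
        assert u.chord_distance_profile(c) == pytest.approx([0, 1.75, 2.5, 1.75, 0], abs=1e-12)

    def test_collinear_all_zero(self):
        c = u.Curve([1, 2, 3, 4], [2, 4, 6, 8])
        assert u.chord_distance_profile(c) == pytest.approx([0, 0, 0, 0], abs=1e-12)

    def test_translation_invariance(self, rng):
        x = np.arange(1.0, 9.0)
        y = rng.uniform(0, 10, 8)
        base = u.chord_distance_profile(u.Curve(x, y))
        shifted = u.chord_distance_profile(u.Curve(x, y + 123.456))
        assert shifted == pytest.approx(base, abs=1e-9)


class TestUik:
    def test_worked_example_selects_three(self):
        est = u.uik(u.Curve([1, 2, 3, 4, 5], [10, 6, 3, 1.5, 1]))
        assert est.selected == 3
        assert est.knee_start == 3.0
        assert est.curve_type == u.CurveType("convex", "decreasing")

    def test_l_shaped_corner(self):
        est = u.uik(u.Curve([1, 2, 3, 4], [10, 1, 0.9, 0.8]))
        assert est.selected == 2

    def test_straight_line_has_no_knee(self):
        with pytest.raises(u.NoKneeError):
            u.uik(u.Curve([1, 2, 3, 4], [2, 4, 6, 8]))

    def test_too_few_points(self):
        with pytest.raises(u.ArgumentError):
            u.Curve([1, 2, 3], [3, 2, 1])

    def test_knee_bounds_and_membership(self, rng):
        x, y = random_convex_decreasing(rng, 12)
        est = u.uik(u.Curve(x, y))
        assert x[0] <= est.knee_start <= est.knee_end <= x[-1]
        assert est.selected in np.round(x).astype(int)

    def test_oracle_equivalence_on_convex_curves(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            x, y = random_convex_decreasing(rng, int(rng.integers(8, 41)))
            est = u.uik(u.Curve(x, y))
            assert est.knee_start == brute_force_knee(x, y)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_unit_invariance(self, a, b, seed):
        """Rescaling either axis by positive constants never moves the knee index."""
        rng = np.random.default_rng(seed)
        x, y = random_convex_decreasing(rng, 15)
        base = u.uik(u.Curve(x, y))
        scaled = u.uik(u.Curve(a * x, b * y))
        assert np.argmin(np.abs(x - base.knee_start)) == np.argmin(
            np.abs(a * x - scaled.knee_start)
        )

    def test_flat_tail_never_moves_knee_left(self, rng):
        """Appending flat tail points shallows the chord, which lifts every
        distance by an amount growing in x: the knee can only stay or move
        right, and knee_end moves weakly right."""
        for _ in range(20):
            x, y = random_convex_decreasing(rng, 10)
            est = u.uik(u.Curve(x, y))
            x2 = np.concatenate([x, x[-1] + np.arange(1, 4)])
            y2 = np.concatenate([y, np.full(3, y[-1])])
            est2 = u.uik(u.Curve(x2, y2))
            assert est2.knee_start >= est.knee_start
            assert est2.knee_end >= est.knee_end

    def test_short_flat_extension_keeps_prominent_knee(self):
        """One flat tail point leaves a prominent knee where it was."""
        c = u.Curve([1, 2, 3, 4, 5], [10, 6, 3, 1.5, 1])
        extended = u.Curve([1, 2, 3, 4, 5, 6], [10, 6, 3, 1.5, 1, 1])
        assert u.uik(extended).selected == u.uik(c).selected == 3

    def test_iterative_mode_refines_leftward(self, rng):
        x, y = random_convex_decreasing(rng, 20)
        default = u.uik(u.Curve(x, y))
        refined = u.uik(u.Curve(x, y), iterative=True)
        assert refined.knee_start <= default.knee_start
        assert x[0] <= refined.knee_start <= x[-1]


class TestSelectRank:
    def test_on_survey_like_object(self):
        class FakeSurvey:
            ranks = [2, 3, 4, 5, 6]
            rss_curve = [10.0, 6.0, 3.0, 2.9, 2.8]

        est = u.select_rank(FakeSurvey())
        assert est.selected == 4

    def test_error_carries_survey_context(self):
        class FakeSurvey:
            ranks = [2, 3, 4, 5]
            rss_curve = [8.0, 6.0, 4.0, 2.0]  # collinear

        with pytest.raises(u.NoKneeError, match="ranks"):
            u.select_rank(FakeSurvey())
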