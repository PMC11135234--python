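"""Knee (elbow) detection by the unit-invariant extremum-distance estimator.

Given a rank-survey curve — candidate ranks on the x-axis and the residual
sum of squares on the y-axis — the knee is the point where a steeply falling
curve turns "flat enough".  The estimator draws the chord joining the curve's
endpoints and locates the extremum of the *vertical* distance between curve
and chord.  Vertical chord distance is invariant under independent positive
rescaling of either axis (rescaling y scales every distance equally;
rescaling x leaves the chord values at the sample points unchanged), so the
selected grid index does not depend on the units of either axis.

The selected rank is the *first* knee abscissa — the first point of maximal
chord distance — matching the convention of taking the first inflection of
the RSS curve as the optimal factorization rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ArgumentError, DegenerateCurveError, NoKneeError

__all__ = [
    "Curve",
    "CurveType",
    "KneeEstimate",
    "check_curve",
    "chord_distance_profile",
    "uik",
    "select_rank",
]

_COLLINEAR_RTOL = 1e-12
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class CurveType:
    convexity: Literal["convex", "concave"]
    trend: Literal["increasing", "decreasing"]


@dataclass
class Curve:
    """A sampled curve: strictly increasing abscissas, at least 4 points."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ArgumentError("x and y must be 1-D arrays of equal length")
        if self.x.size < 4:
            raise ArgumentError(f"a curve needs >= 4 points, got {self.x.size}")
        if not np.all(np.diff(self.x) > 0):
            raise ArgumentError("x must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ArgumentError("curve contains non-finite values")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class KneeEstimate:
    """Classified curve plus knee abscissas and the selected grid point."""

    curve_type: CurveType
    knee_start: float
    knee_end: float
    selected: int


def _chord(c: Curve) -> np.ndarray:
    x0, x1 = c.x[0], c.x[-1]
    y0, y1 = c.y[0], c.y[-1]
    return y0 + (c.x - x0) * (y1 - y0) / (x1 - x0)


def check_curve(c: Curve) -> CurveType:
    """Classify trend (endpoint comparison) and convexity (chord side).

    The trend is the sign of ``y[-1] - y[0]``; convexity is decided by which
    side of the endpoint chord the curve predominantly lies on (below the
    chord means convex).  Constant curves have neither and raise.
    """
    y = c.y
    if np.all(y == y[0]):
        raise DegenerateCurveError("constant curve: trend and convexity undefined")
    trend = "decreasing" if y[-1] < y[0] else "increasing"
    deviation = float(np.sum(y - _chord(c)))
    convexity = "concave" if deviation > 0 else "convex"
    return CurveType(convexity=convexity, trend=trend)


def chord_distance_profile(c: Curve) -> np.ndarray:
    """Vertical distance of every point from the endpoint chord.

    Endpoints are on the chord, so the profile begins and ends at 0.  The
    profile is invariant under adding a constant to all y and scales linearly
    with any positive rescaling of y.
    """
    return np.abs(c.y - _chord(c))


def _extremum_band(d: np.ndarray) -> tuple[int, int]:
    """First and last index attaining the profile maximum within 1e-9 relative."""
    dmax = float(d.max())
    band = np.flatnonzero(d >= dmax * (1.0 - _TIE_RTOL))
    return int(band[0]), int(band[-1])


def uik(c: Curve, iterative: bool = False) -> KneeEstimate:
    """Locate the knee of a curve via the chord-distance extremum.

    ``knee_start`` and ``knee_end`` are the abscissas of the first and last
    points whose chord distance ties (to 1e-9 relative) the global maximum;
    the selected point is ``knee_start``, the first such grid point.  With
    ``iterative=True`` the chord is repeatedly re-drawn over the sub-curve up
    to the current knee and the extremum re-located until it stabilizes — a
    refinement that sharpens the estimate on long flat tails; the default
    single-chord extremum is what the rank-selection pipeline uses.

    Raises
    ------
    NoKneeError
        If the points are collinear (every chord distance ~ 0).
    DegenerateCurveError
        If the curve is constant.
    """
    ct = check_curve(c)
    d = chord_distance_profile(c)
    span = float(c.y.max() - c.y.min())
    if span == 0.0 or d.max() <= _COLLINEAR_RTOL * span:
        raise NoKneeError("curve is a straight line: no knee exists")
    i0, i1 = _extremum_band(d)

    if iterative:
        # Re-draw the chord over [0 .. knee] and re-locate; stops when the
        # knee index is stable or the sub-curve is too short to split again.
        lo, hi = 0, i1
        sel = i0
        while hi - lo + 1 >= 4:
            sub = Curve(c.x[lo : hi + 1], c.y[lo : hi + 1])
            dsub = chord_distance_profile(sub)
            if dsub.max() <= _COLLINEAR_RTOL * max(span, 1.0):
                break
            j0, j1 = _extremum_band(dsub)
            new_sel = lo + j0
            if new_sel == sel:
                break
            sel, hi = new_sel, lo + j1
        i0 = sel

    knee_start = float(c.x[i0])
    knee_end = float(c.x[i1])
    # Snap to the nearest grid abscissa (ties toward the smaller rank).
    gaps = np.abs(c.x - knee_start)
    sel_idx = int(np.flatnonzero(gaps == gaps.min())[0])
    return KneeEstimate(
        curve_type=ct,
        knee_start=knee_start,
        knee_end=knee_end,
        selected=int(round(c.x[sel_idx])),
    )


def select_rank(survey) -> KneeEstimate:
    """Apply the knee estimator to a rank survey's RSS curve.

    Accepts a :class:`~uiknmf.survey.SurveyResult`; the selected value is the
    recommended factorization rank.
    """
    try:
        curve = Curve(np.asarray(survey.ranks, dtype=float), np.asarray(survey.rss_curve))
        return uik(curve)
    except (ArgumentError, NoKneeError, DegenerateCurveError) as exc:
        raise type(exc)(
            f"rank selection on survey over ranks {list(survey.ranks)} failed: {exc}"
        ) from exc
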