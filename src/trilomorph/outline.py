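"""From two digitized open curves to one closed 128-semilandmark outline.

The digitization protocol records a cephalon as two open curves anchored at
the genal-spine tips: an anterior curve (left tip, around the front, to the
right tip) and a posterior curve (right tip, around the rear, back to the
left tip).  Each is resampled to 64 equally spaced semilandmarks, the
near-duplicate junction points are merged, and the resulting closed contour
is resampled at equal arc length to exactly 128 points with a fixed positive
(counter-clockwise) winding.  The two junction positions are carried along as
anchor indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEMILANDMARKS_PER_CURVE = 64
OUTLINE_POINTS = 128


class DegenerateCurveError(ValueError):
    """Curve with zero total arc length cannot be resampled."""


class AssemblyError(ValueError):
    """Curves do not meet at their junctions within tolerance."""


@dataclass
class ClosedOutline:
    """A closed simple polygon of exactly 128 points, positively wound.

    ``anchor_indices`` are the positions of the two curve-junction points
    (genal-spine tips); index 0 is always the left-tip junction.
    """

    points: np.ndarray
    anchor_indices: tuple[int, int] = (0, OUTLINE_POINTS // 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (OUTLINE_POINTS, 2):
            raise ValueError(
                f"closed outline must have exactly {OUTLINE_POINTS} points, "
                f"got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("outline contains non-finite coordinates")
        d = np.linalg.norm(np.diff(self.points, axis=0, append=self.points[:1]), axis=1)
        if np.any(d == 0):
            raise ValueError("outline has consecutive duplicate points")
        if signed_area(self.points) <= 0:
            raise ValueError("outline winding must give positive signed area")

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (closure implicit)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_curve(curve: np.ndarray, k: int = SEMILANDMARKS_PER_CURVE) -> np.ndarray:
    """Resample an open polyline to ``k`` points at equal arc-length spacing.

    Interpolation is piecewise linear along the input polyline; the first and
    last output points coincide with the input endpoints exactly.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
        raise ValueError("curve must be an (m, 2) array with m >= 2")
    if k < 2:
        raise ValueError("k must be >= 2")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise DegenerateCurveError("curve has zero total arc length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.column_stack(
        [np.interp(targets, s, curve[:, 0]), np.interp(targets, s, curve[:, 1])]
    )
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


def _resample_closed(points: np.ndarray, k: int) -> np.ndarray:
    """Equal arc-length resampling around a closed polygon, keeping point 0."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise DegenerateCurveError("closed contour has zero perimeter")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k, endpoint=False)
    out = np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )
    out[0] = points[0]
    return out


def assemble_outline(
    anterior: np.ndarray,
    posterior: np.ndarray,
    junction_tolerance: float = 0.01,
) -> ClosedOutline:
    """Join the anterior and posterior 64-point curves into a closed outline.

    The anterior curve must end where the posterior starts (right genal-spine
    tip) and the posterior must end where the anterior starts (left tip),
    within ``junction_tolerance`` times the outline diameter.  The duplicated
    junction coordinates are merged by averaging, and the merged contour is
    resampled at equal arc length to exactly 128 points starting at the left
    junction, re-oriented to positive winding.
    """
    anterior = np.asarray(anterior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    for name, c in (("anterior", anterior), ("posterior", posterior)):
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
            raise ValueError(f"{name} curve must be an (m, 2) array with m >= 2")

    allpts = np.vstack([anterior, posterior])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    diameter = float(np.linalg.norm(hi - lo))
    if diameter <= 0:
        raise DegenerateCurveError("curves are degenerate (zero diameter)")

    gap_right = float(np.linalg.norm(anterior[-1] - posterior[0]))
    gap_left = float(np.linalg.norm(posterior[-1] - anterior[0]))
    limit = junction_tolerance * diameter
    if gap_right > limit or gap_left > limit:
        raise AssemblyError(
            "junction mismatch: right gap "
            f"{gap_right:.6g}, left gap {gap_left:.6g} exceed tolerance "
            f"{limit:.6g} ({junction_tolerance:.3g} x diameter {diameter:.6g})"
        )

    left_junction = 0.5 * (posterior[-1] + anterior[0])
    right_junction = 0.5 * (anterior[-1] + posterior[0])
    # each junction counted once: left, anterior interior, right, posterior interior
    chain = np.vstack(
        [left_junction, anterior[1:-1], right_junction, posterior[1:-1]]
    )
    # drop accidental consecutive duplicates (can appear when a spine collapses)
    keep = np.ones(len(chain), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(chain, axis=0), axis=1) > 1e-12 * diameter
    chain = chain[keep]

    points = _resample_closed(chain, OUTLINE_POINTS)
    if signed_area(points) < 0:
        # reverse while keeping the left junction at index 0
        points = np.vstack([points[:1], points[:0:-1]])

    # anchor 1 is the resampled point nearest the right junction
    right_idx = int(np.argmin(np.linalg.norm(points - right_junction, axis=1)))
    return ClosedOutline(points=points, anchor_indices=(0, right_idx))


def is_simple_polygon(points: np.ndarray) -> bool:
    """True when the closed polygon has no self-intersections."""
    from shapely.geometry import LinearRing

    try:
        return LinearRing(np.asarray(points, dtype=float)).is_simple
    except Exception:
        return False
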