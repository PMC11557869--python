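"""Shared fixtures: geometric test shapes and a dense-quadrature EFA oracle.

The oracle utilities here are written independently of the package internals
(plain numpy interpolation / trapezoid integration) so that implementation
and oracle can disagree.
"""

from __future__ import annotations

import numpy as np
import pytest


def densify_polygon(vertices: np.ndarray, k: int) -> np.ndarray:
    """Independent equal-arc-length resampler for closed polygons (test oracle)."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], k, endpoint=False)
    return np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )


def efa_quadrature_oracle(points: np.ndarray, n_harmonics: int, refine: int = 10_000) -> np.ndarray:
    """Brute-force trapezoid integration of the elliptic Fourier integrals.

    Integrates x(t)cos/sin and y(t)cos/sin over a dense arc-length refinement
    of the polygon (polygon vertices are included in the grid so the
    piecewise-linear geometry is represented exactly).
    """
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    T = s[-1]
    grid = np.unique(np.concatenate([np.linspace(0.0, T, refine + 1), s]))
    x = np.interp(grid, s, closed[:, 0])
    y = np.interp(grid, s, closed[:, 1])
    out = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * n * grid / T)
        sn = np.sin(2 * np.pi * n * grid / T)
        out[n - 1] = [
            np.trapezoid(x * c, grid) * 2 / T,
            np.trapezoid(x * sn, grid) * 2 / T,
            np.trapezoid(y * c, grid) * 2 / T,
            np.trapezoid(y * sn, grid) * 2 / T,
        ]
    return out


def segments_self_intersect(points: np.ndarray) -> bool:
    """Brute-force pairwise segment intersection test for a closed polygon."""
    closed = np.vstack([points, points[:1]])
    n = len(points)

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        a1, a2 = closed[i], closed[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            b1, b2 = closed[j], closed[j + 1]
            d1, d2 = ccw(a1, a2, b1), ccw(a1, a2, b2)
            d3, d4 = ccw(b1, b2, a1), ccw(b1, b2, a2)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


@pytest.fixture
def ellipse_outline() -> np.ndarray:
    """2:1 ellipse sampled at equal arc length, 128 points."""
    t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    dense = np.column_stack([2 * np.cos(t), np.sin(t)])
    return densify_polygon(dense, 128)


@pytest.fixture
def square_outline() -> np.ndarray:
    """Unit square densified to 128 equally spaced points."""
    return densify_polygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), 128)


@pytest.fixture
def triangle_outline() -> np.ndarray:
    """A scalene triangle densified to 128 points (rounded-corner-free)."""
    return densify_polygon(np.array([[0, 0], [2, 0], [0.7, 1.5]], float), 128)


@pytest.fixture
def smooth_blob() -> np.ndarray:
    """A smooth asymmetric closed curve, 128 equally spaced points."""
    t = np.linspace(0, 2 * np.pi, 8192, endpoint=False)
    r = 1 + 0.25 * np.cos(2 * t) + 0.1 * np.sin(3 * t) + 0.05 * np.cos(5 * t)
    dense = np.column_stack([r * np.cos(t), r * np.sin(t)])
    return densify_polygon(dense, 128)


@pytest.fixture
def cephalon_outline():
    from trilomorph.synthetic import CephalonParams, generate_cephalon

    return generate_cephalon(CephalonParams(), rng=np.random.default_rng(11))
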