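"""PCA morphospace over normalized coefficient matrices, plus hull geometry.

The ordination is a covariance-matrix eigendecomposition (no correlation
scaling): coefficient columns share units, and scaling them would inflate the
contribution of high-order harmonics that carry mostly digitization noise.
A deterministic sign convention (the largest-magnitude loading on each axis is
made positive) keeps scores bit-reproducible across runs and platforms.

Downstream analytics operate on the retained principal components — two by
default, matching the convention of discarding components that mostly encode
specimen compression and distortion noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError


@dataclass
class MorphospaceModel:
    mean_vector: np.ndarray
    axes: np.ndarray  # (p, p), columns are loading vectors
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    scores: pd.DataFrame  # n_specimens x n_axes, columns PC1..PCp
    retained_dims: int = 2

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.retained_dims]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_vector) @ self.axes


@dataclass
class GroupGeometry:
    group_label: str
    n: int
    centroid: np.ndarray
    hull_area: float
    hull_vertices: np.ndarray
    degenerate: bool = False  # n < 3 or collinear: hull area is 0 by convention


def fit_pca(
    X: np.ndarray | pd.DataFrame,
    retained_dims: int = 2,
    specimen_ids: list[str] | None = None,
) -> MorphospaceModel:
    """Covariance-based PCA with a deterministic sign rule."""
    if isinstance(X, pd.DataFrame):
        if specimen_ids is None:
            specimen_ids = list(X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    if not 1 <= retained_dims <= p:
        raise ValueError(f"retained_dims must be in [1, {p}]")

    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading positive per axis
    for j in range(p):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = Xc @ eigvecs
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(n)]
    scores_df = pd.DataFrame(
        scores, index=specimen_ids, columns=[f"PC{j + 1}" for j in range(p)]
    )
    return MorphospaceModel(
        mean_vector=mean,
        axes=eigvecs,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=scores_df,
        retained_dims=retained_dims,
    )


def hull_area(points: np.ndarray) -> float:
    """Area of the 2D convex hull; 0 for fewer than 3 distinct/non-collinear points."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D: volume is area
    except QhullError:
        return 0.0  # collinear input


def hull_vertices(points: np.ndarray) -> np.ndarray:
    """Ordered hull vertex coordinates (counter-clockwise); degenerate -> empty."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] < 3:
        return np.empty((0, 2))
    try:
        h = ConvexHull(pts)
    except QhullError:
        return np.empty((0, 2))
    return pts[h.vertices]


def group_geometry(scores: pd.DataFrame, labels: pd.Series | np.ndarray) -> list[GroupGeometry]:
    """Per-group centroid, convex hull area and vertices in retained-PC space.

    Groups with fewer than 3 points (or collinear points) get hull area 0 and
    a ``degenerate`` flag; they are reported, never dropped.
    """
    labels = pd.Series(np.asarray(labels), index=scores.index)
    out: list[GroupGeometry] = []
    for label in labels.unique():
        pts = scores.loc[labels == label].to_numpy(dtype=float)
        area = hull_area(pts)
        out.append(
            GroupGeometry(
                group_label=str(label),
                n=len(pts),
                centroid=pts.mean(axis=0),
                hull_area=area,
                hull_vertices=hull_vertices(pts),
                degenerate=area == 0.0,
            )
        )
    return out


def centroid_distances(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric matrix of Euclidean distances between group mean points."""
    if not groups:
        raise ValueError("need at least one group")
    labels = list(groups)
    cents = []
    for label in labels:
        pts = np.asarray(groups[label], dtype=float)
        if pts.size == 0:
            raise ValueError(f"group {label!r} is empty")
        cents.append(np.atleast_2d(pts).mean(axis=0))
    C = np.vstack(cents)
    diff = C[:, None, :] - C[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    return pd.DataFrame(D, index=labels, columns=labels)


def plot_morphospace(
    scores: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    ax=None,
    show_hulls: bool = True,
):
    """Minimal PC1-PC2 scatter with group hulls (smoke-test plotting only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    labels = pd.Series(np.asarray(labels), index=scores.index)
    for label in labels.unique():
        pts = scores.loc[labels == label].iloc[:, :2].to_numpy()
        sc = ax.scatter(pts[:, 0], pts[:, 1], s=8, label=str(label))
        if show_hulls:
            hv = hull_vertices(pts)
            if len(hv):
                closed = np.vstack([hv, hv[:1]])
                ax.plot(closed[:, 0], closed[:, 1], lw=0.8, color=sc.get_facecolor()[0])
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    ax.legend(fontsize=6)
    return ax
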