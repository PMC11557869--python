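"""Group predictability (LDA leave-one-out) and natural clustering (k-means).

The cross-validation table asks: if a specimen of known group were a new
find, which group would a discriminant model trained on everything else
assign it to?  Rows are true groups, columns predicted groups, entries
row-normalized proportions.  Priors default to group frequencies.

The k-means scan fits k = k_min..k_max with multiple seeded restarts and
picks k by the elbow rule — the largest second difference of the
within-cluster sum of squares curve (the sharpest drop in marginal gain),
ties resolved toward smaller k.  A manual override reproduces visually
chosen k values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from trilomorph.efa import CoefficientSet, mean_shape


@dataclass
class CrossValidationTable:
    labels: list[str]
    proportions: pd.DataFrame  # true (rows) x predicted (cols)

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.proportions), index=self.labels)


@dataclass
class KMeansScan:
    k_values: np.ndarray
    wcss: np.ndarray
    chosen_k: int
    assignments: np.ndarray
    restarts: int
    seed: int


def lda_loo_table(
    scores: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    uniform_priors: bool = False,
) -> CrossValidationTable:
    """Leave-one-out LDA prediction proportions, true group x predicted group.

    Gaussian LDA with pooled within-group covariance; priors proportional to
    group sizes unless ``uniform_priors``.  Every specimen is predicted by a
    model fit on all the others.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    uniq = sorted(np.unique(y))
    if len(uniq) < 2:
        raise ValueError("LDA needs at least 2 groups")
    p = X.shape[1]
    for g in uniq:
        if np.sum(y == g) < p + 1:
            raise ValueError(
                f"group {g!r} too small for {p}-dimensional LDA (need n >= {p + 1})"
            )

    n = len(y)
    predicted = np.empty(n, dtype=object)
    priors = np.full(len(uniq), 1.0 / len(uniq)) if uniform_priors else None
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = LinearDiscriminantAnalysis(solver="svd", priors=priors)
        try:
            clf.fit(X[mask], y[mask])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance; reduce dimensions before LDA"
            ) from exc
        predicted[i] = clf.predict(X[i : i + 1])[0]

    counts = pd.crosstab(pd.Series(y, name="true"), pd.Series(predicted, name="predicted"))
    counts = counts.reindex(index=uniq, columns=uniq, fill_value=0)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return CrossValidationTable(labels=list(uniq), proportions=proportions)


def kmeans_scan(
    scores: np.ndarray | pd.DataFrame,
    k_min: int = 1,
    k_max: int = 10,
    restarts: int = 25,
    seed: int = 0,
    k_override: int | None = None,
) -> KMeansScan:
    """Scan k-means over k and select k by the elbow rule.

    For each k the best of ``restarts`` seeded runs is kept; the scan is
    fully reproducible for a fixed seed.  ``k_override`` replaces the elbow
    choice (assignments are refit at that k) for manually selected cluster
    counts.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    if n < k_max:
        raise ValueError(f"n={n} specimens cannot support k_max={k_max} clusters")

    ks = np.arange(k_min, k_max + 1)
    wcss = np.empty(len(ks))
    fits = {}
    for j, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=restarts, random_state=seed)
        km.fit(X)
        wcss[j] = km.inertia_
        fits[int(k)] = km

    chosen = k_override if k_override is not None else _elbow(ks, wcss)
    if chosen not in fits:
        raise ValueError(f"chosen k={chosen} outside scanned range {k_min}..{k_max}")
    return KMeansScan(
        k_values=ks,
        wcss=wcss,
        chosen_k=int(chosen),
        assignments=fits[int(chosen)].labels_.copy(),
        restarts=restarts,
        seed=seed,
    )


def _elbow(ks: np.ndarray, wcss: np.ndarray) -> int:
    """k maximizing the second difference of wcss; ties break to smaller k."""
    if len(ks) < 3:
        return int(ks[0])
    second = wcss[:-2] - 2.0 * wcss[1:-1] + wcss[2:]  # indexed by interior ks
    best = int(np.argmax(second))  # argmax returns the first (smallest-k) maximum
    return int(ks[1 + best])


def cluster_mean_shapes(
    scan: KMeansScan,
    coefficient_sets: Sequence[CoefficientSet],
    n_points: int = 128,
) -> dict[int, np.ndarray]:
    """Mean outline shape per k-means cluster (empty clusters are skipped)."""
    if len(coefficient_sets) != len(scan.assignments):
        raise ValueError(
            f"{len(coefficient_sets)} coefficient sets but "
            f"{len(scan.assignments)} cluster assignments"
        )
    shapes: dict[int, np.ndarray] = {}
    for cluster in range(scan.chosen_k):
        members = [
            c for c, a in zip(coefficient_sets, scan.assignments) if a == cluster
        ]
        if not members:
            continue
        shapes[cluster] = mean_shape(members, n_points=n_points)
    return shapes
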