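"""Disparity metrics and group-comparison statistics on morphospace scores.

Two complementary disparity metrics are used.  The sum of variances (SoV,
per-dimension sample variances summed) measures how tightly specimens pack
within occupied space; the sum of ranges (SoR, per-dimension max minus min
summed) measures the breadth of occupation and is more outlier-sensitive.
Group comparisons bootstrap each metric (resampling specimens within a group
with replacement) and compare the bootstrap distributions with Welch t-tests
under a Bonferroni-corrected alpha of 0.05 / C(g, 2).  Differences in score
location are tested with one-way MANOVA (Pillai's trace by default, Wilks'
lambda via flag) using the standard approximate F transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class GroupDisparity:
    group_label: str
    n: int
    sov: float
    sor: float
    bootstrap_draws: np.ndarray  # (replicates, 2): columns (sov, sor)
    seed: int


@dataclass
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    corrected_alpha: float = 0.05
    df: tuple[float, float] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


def sum_of_variances(points: np.ndarray) -> float:
    """Sum over dimensions of the sample variance (n - 1 denominator)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("sum of variances needs at least 2 points")
    return float(np.sum(np.var(pts, axis=0, ddof=1)))


def sum_of_ranges(points: np.ndarray) -> float:
    """Sum over dimensions of (max - min)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("sum of ranges needs at least 1 point")
    return float(np.sum(pts.max(axis=0) - pts.min(axis=0)))


def bootstrap_disparity(
    points: np.ndarray,
    replicates: int = 500,
    seed: int = 0,
    group_label: str = "group",
) -> GroupDisparity:
    """Bootstrap SoV and SoR by resampling specimens with replacement.

    The same seed always reproduces the same draws.  No rarefaction is
    applied: every resample has the observed group size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 points")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((replicates, 2))
    for r in range(replicates):
        sample = pts[rng.integers(0, n, size=n)]
        draws[r, 0] = sum_of_variances(sample)
        draws[r, 1] = sum_of_ranges(sample)
    return GroupDisparity(
        group_label=group_label,
        n=n,
        sov=sum_of_variances(pts),
        sor=sum_of_ranges(pts),
        bootstrap_draws=draws,
        seed=seed,
    )


def bonferroni_alpha(n_groups: int, alpha: float = 0.05) -> float:
    """Alpha divided by the number of unordered group pairings C(g, 2)."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    return alpha / comb(n_groups, 2)


_METRIC_COLUMN = {"sov": 0, "sor": 1}


def pairwise_disparity_tests(
    disparities: list[GroupDisparity],
    metric: str = "sov",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests between every pair of bootstrap metric distributions.

    Returns one row per unordered pair with the statistic, p-value, the
    Bonferroni-corrected alpha and the significance call.
    """
    if metric not in _METRIC_COLUMN:
        raise ValueError("metric must be 'sov' or 'sor'")
    if len(disparities) < 2:
        raise ValueError("need at least 2 groups")
    for d in disparities:
        if d.bootstrap_draws is None or len(d.bootstrap_draws) == 0:
            raise ValueError(f"group {d.group_label!r} has no bootstrap draws")
    col = _METRIC_COLUMN[metric]
    corrected = bonferroni_alpha(len(disparities), alpha)
    rows = []
    for d1, d2 in combinations(disparities, 2):
        t, p = stats.ttest_ind(
            d1.bootstrap_draws[:, col], d2.bootstrap_draws[:, col], equal_var=False
        )
        rows.append(
            {
                "group1": d1.group_label,
                "group2": d2.group_label,
                "metric": metric,
                "statistic": float(t),
                "p_value": float(p),
                "corrected_alpha": corrected,
                "significant": bool(p < corrected),
            }
        )
    return pd.DataFrame(rows)


def _manova_oneway(X: np.ndarray, labels: np.ndarray, stat: str) -> TestResult:
    groups = [X[labels == g] for g in np.unique(labels)]
    g = len(groups)
    N, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in groups:
        m = grp.mean(axis=0)
        dev = grp - m
        W += dev.T @ dev
        dm = (m - grand)[:, None]
        B += len(grp) * (dm @ dm.T)
    # eigenvalues of W^{-1} B via the symmetric generalized problem
    eigvals = linalg.eigh(B, W, eigvals_only=True)
    eigvals = np.clip(eigvals, 0.0, None)

    s = min(p, g - 1)
    m_par = (abs(p - g + 1) - 1) / 2.0
    n_par = (N - g - p - 1) / 2.0

    if stat == "pillai":
        V = float(np.sum(eigvals / (1.0 + eigvals)))
        df1 = s * (2 * m_par + s + 1)
        df2 = s * (2 * n_par + s + 1)
        F = (df2 / df1) * (V / (s - V))
        name = "Pillai"
        value = V
    elif stat == "wilks":
        lam = float(np.prod(1.0 / (1.0 + eigvals)))
        # Rao's F approximation
        t_num = p * p + (g - 1) ** 2 - 5
        t_par = np.sqrt((p**2 * (g - 1) ** 2 - 4) / t_num) if t_num > 0 else 1.0
        df1 = p * (g - 1)
        df2 = t_par * ((N - 1) - (p + g) / 2.0) - (p * (g - 1) - 2) / 2.0
        lam_t = lam ** (1.0 / t_par)
        F = ((1 - lam_t) / lam_t) * (df2 / df1)
        name = "Wilks"
        value = lam
    else:
        raise ValueError("stat must be 'pillai' or 'wilks'")
    p_value = float(stats.f.sf(F, df1, df2))
    return TestResult(
        statistic_name=f"MANOVA_{name}_F",
        statistic_value=float(F),
        p_value=p_value,
        df=(float(df1), float(df2)),
    )


def manova_test(
    scores: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    pairwise: bool = False,
    alpha: float = 0.05,
    stat: str = "pillai",
) -> TestResult | pd.DataFrame:
    """One-way MANOVA on retained-PC scores.

    With ``pairwise=True``, every unordered pair of groups is tested and the
    Bonferroni-corrected alpha (alpha / C(g, 2)) is applied.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    p = X.shape[1]
    for g in uniq:
        n_g = int(np.sum(labels == g))
        if n_g < p + 1:
            raise ValueError(
                f"group {g!r} has n={n_g}, below the minimum {p + 1} for {p} dimensions"
            )

    if not pairwise:
        res = _manova_oneway(X, labels, stat)
        res.corrected_alpha = alpha
        return res

    corrected = bonferroni_alpha(len(uniq), alpha)
    rows = []
    for g1, g2 in combinations(uniq, 2):
        mask = (labels == g1) | (labels == g2)
        res = _manova_oneway(X[mask], labels[mask], stat)
        rows.append(
            {
                "group1": str(g1),
                "group2": str(g2),
                "statistic": res.statistic_name,
                "F": res.statistic_value,
                "p_value": res.p_value,
                "corrected_alpha": corrected,
                "significant": bool(res.p_value < corrected),
            }
        )
    return pd.DataFrame(rows)


def disparity_table(disparities: list[GroupDisparity]) -> pd.DataFrame:
    """Observed SoV/SoR plus bootstrap means and 2.5/97.5% quantiles per group."""
    rows = []
    for d in disparities:
        sov_d = d.bootstrap_draws[:, 0]
        sor_d = d.bootstrap_draws[:, 1]
        rows.append(
            {
                "group": d.group_label,
                "n": d.n,
                "sov": d.sov,
                "sor": d.sor,
                "sov_boot_mean": float(sov_d.mean()),
                "sov_boot_q025": float(np.quantile(sov_d, 0.025)),
                "sov_boot_q975": float(np.quantile(sov_d, 0.975)),
                "sor_boot_mean": float(sor_d.mean()),
                "sor_boot_q025": float(np.quantile(sor_d, 0.025)),
                "sor_boot_q975": float(np.quantile(sor_d, 0.975)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
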