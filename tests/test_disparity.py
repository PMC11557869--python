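"""Disparity metrics, bootstrap machinery, MANOVA and Bonferroni arithmetic."""

import numpy as np
import pytest

from trilomorph import disparity

TWO_POINTS = np.array([[0.0, 0.0], [1.0, 2.0]])


class TestMetrics:
    def test_hand_computed_sov(self):
        # sample variances: 0.5 on x, 2.0 on y
        assert disparity.sum_of_variances(TWO_POINTS) == pytest.approx(2.5)

    def test_hand_computed_sor(self):
        assert disparity.sum_of_ranges(TWO_POINTS) == pytest.approx(3.0)

    def test_identical_points_degenerate(self):
        same = np.ones((10, 2))
        assert disparity.sum_of_variances(same) == 0.0
        assert disparity.sum_of_ranges(same) == 0.0
        assert disparity.sum_of_ranges(np.array([[3.0, 4.0]])) == 0.0

    def test_scaling_laws(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        c = 3.7
        assert disparity.sum_of_variances(c * pts) == pytest.approx(
            c**2 * disparity.sum_of_variances(pts)
        )
        assert disparity.sum_of_ranges(c * pts) == pytest.approx(
            c * disparity.sum_of_ranges(pts)
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 2))
        shift = np.array([100.0, -40.0])
        assert disparity.sum_of_variances(pts + shift) == pytest.approx(
            disparity.sum_of_variances(pts), rel=1e-9
        )
        assert disparity.sum_of_ranges(pts + shift) == pytest.approx(
            disparity.sum_of_ranges(pts), rel=1e-9
        )

    def test_interior_point_leaves_sor_unchanged(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 2))
        inner = np.vstack([pts, pts.mean(axis=0)])
        assert disparity.sum_of_ranges(inner) == disparity.sum_of_ranges(pts)

    def test_single_point_sov_rejected(self):
        with pytest.raises(ValueError):
            disparity.sum_of_variances(np.array([[1.0, 2.0]]))


class TestBootstrap:
    def test_fixed_seed_reproduces_draws(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 2))
        d1 = disparity.bootstrap_disparity(pts, replicates=100, seed=11)
        d2 = disparity.bootstrap_disparity(pts, replicates=100, seed=11)
        np.testing.assert_array_equal(d1.bootstrap_draws, d2.bootstrap_draws)

    def test_draws_nonnegative_and_sor_bounded_by_observed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(35, 2))
        d = disparity.bootstrap_disparity(pts, replicates=200, seed=5)
        assert np.all(d.bootstrap_draws >= 0)
        # resampling cannot exceed the observed range on any axis
        assert np.all(d.bootstrap_draws[:, 1] <= d.sor + 1e-12)

    def test_bootstrap_consistency_at_large_n(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(500, 2))
        d = disparity.bootstrap_disparity(pts, replicates=500, seed=7)
        assert d.bootstrap_draws[:, 0].mean() == pytest.approx(d.sov, rel=0.05)

    def test_replicate_validation(self):
        with pytest.raises(ValueError):
            disparity.bootstrap_disparity(TWO_POINTS, replicates=0, seed=0)


class TestBonferroni:
    def test_twelve_groups_matches_printed_threshold(self):
        # 0.05 / C(12,2) = 0.05 / 66
        assert disparity.bonferroni_alpha(12) == pytest.approx(7.576e-4, rel=1e-4)

    def test_six_groups(self):
        assert disparity.bonferroni_alpha(6) == pytest.approx(0.05 / 15)

    def test_two_groups_uncorrected(self):
        assert disparity.bonferroni_alpha(2) == pytest.approx(0.05)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            disparity.bonferroni_alpha(1)


class TestPairwiseDisparityTests:
    def _disparities(self, n_groups, seed=0, replicates=100):
        rng = np.random.default_rng(seed)
        return [
            disparity.bootstrap_disparity(
                rng.normal(size=(30, 2)), replicates=replicates, seed=seed + i,
                group_label=f"g{i}",
            )
            for i in range(n_groups)
        ]

    def test_pair_count(self):
        table = disparity.pairwise_disparity_tests(self._disparities(5))
        assert len(table) == 10  # C(5,2)
        np.testing.assert_allclose(table["corrected_alpha"], 0.05 / 10)

    def test_same_cloud_rarely_significant(self):
        # both groups bootstrap the same points: Welch t on equal
        # distributions should stay below the corrected alpha rarely
        rng = np.random.default_rng(9)
        nonsig = 0
        repeats = 40
        for r in range(repeats):
            pts = rng.normal(size=(50, 2))
            d1 = disparity.bootstrap_disparity(pts, replicates=300, seed=1000 + r)
            d2 = disparity.bootstrap_disparity(pts, replicates=300, seed=5000 + r)
            table = disparity.pairwise_disparity_tests([d1, d2], metric="sov")
            nonsig += not table["significant"].iloc[0]
        assert nonsig / repeats >= 0.9

    def test_missing_draws_rejected(self):
        d = self._disparities(2)
        d[0].bootstrap_draws = np.empty((0, 2))
        with pytest.raises(ValueError, match="draws"):
            disparity.pairwise_disparity_tests(d)


class TestManova:
    def _two_groups(self, delta, n=50, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(delta, 1, (n, 2))])
        return X, np.repeat(["a", "b"], n)

    def test_matches_statsmodels_pillai(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        X, labels = self._two_groups(0.7, seed=12)
        ours = disparity.manova_test(X, labels)
        df = pd.DataFrame(X, columns=["y1", "y2"])
        df["g"] = labels
        sm = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        row = sm.results["g"]["stat"].loc["Pillai's trace"]
        assert ours.statistic_value == pytest.approx(float(row["F Value"]), rel=1e-8)
        assert ours.p_value == pytest.approx(float(row["Pr > F"]), rel=1e-6)

    def test_wilks_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        X, labels = self._two_groups(0.4, seed=13)
        ours = disparity.manova_test(X, labels, stat="wilks")
        df = pd.DataFrame(X, columns=["y1", "y2"])
        df["g"] = labels
        sm = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        row = sm.results["g"]["stat"].loc["Wilks' lambda"]
        assert ours.statistic_value == pytest.approx(float(row["F Value"]), rel=1e-8)

    def test_power_on_widely_separated_groups(self):
        X, labels = self._two_groups(10.0, seed=2)
        assert disparity.manova_test(X, labels).p_value < 1e-10

    def test_small_group_rejected_by_name(self):
        X = np.vstack([np.random.default_rng(0).normal(size=(10, 2)), [[0, 0], [1, 1]]])
        labels = np.array(["big"] * 10 + ["small"] * 2)
        with pytest.raises(ValueError, match="small"):
            disparity.manova_test(X, labels)

    def test_pairwise_mode_counts_and_alpha(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2))
        labels = np.repeat(["a", "b", "c"], 20)
        table = disparity.manova_test(X, labels, pairwise=True)
        assert len(table) == 3
        np.testing.assert_allclose(table["corrected_alpha"], 0.05 / 3)


class TestVarianceRecovery:
    def test_sov_orders_groups_by_true_covariance(self):
        # B has 4x A's covariance: estimated SoV_B should exceed SoV_A in
        # at least 95% of seeds at n=50 per group
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1.0, (50, 2))
            b = rng.normal(0, 2.0, (50, 2))  # 4x covariance
            hits += disparity.sum_of_variances(b) > disparity.sum_of_variances(a)
        assert hits / 50 >= 0.95
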