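"""Elliptic Fourier decomposition, normalization and harmonic selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trilomorph import efa
from tests.conftest import densify_polygon, efa_quadrature_oracle


def _natural_ellipse(a=2.0, b=1.0, k=1 << 16):
    t = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


class TestForward:
    def test_ellipse_closed_form_in_natural_parameter(self):
        cs = efa.efa_forward(_natural_ellipse(), 8, parameterization="uniform")
        np.testing.assert_allclose(cs.harmonics[0], [2, 0, 0, 1], atol=1e-8)
        prof = efa.harmonic_power(cs)
        assert prof.cumulative_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_translation_only_enters_dc_terms(self, smooth_blob):
        cs = efa.efa_forward(smooth_blob, 10)
        shifted = efa.efa_forward(smooth_blob + np.array([10.0, -3.0]), 10)
        np.testing.assert_allclose(shifted.harmonics, cs.harmonics, atol=1e-12)
        assert shifted.dc[0] - cs.dc[0] == pytest.approx(10.0, abs=1e-9)
        assert shifted.dc[1] - cs.dc[1] == pytest.approx(-3.0, abs=1e-9)

    def test_square_matches_quadrature_oracle(self, square_outline):
        cs = efa.efa_forward(square_outline, 10)
        oracle = efa_quadrature_oracle(square_outline, 10)
        np.testing.assert_allclose(cs.harmonics, oracle, atol=1e-6)

    def test_harmonic_range_validated(self, smooth_blob):
        with pytest.raises(ValueError):
            efa.efa_forward(smooth_blob, 0)
        with pytest.raises(ValueError):
            efa.efa_forward(smooth_blob, 65)  # 128-point outline caps at 64


class TestInverse:
    def test_pure_first_harmonic_is_an_ellipse(self):
        cs = efa.CoefficientSet(
            specimen_id="e", harmonics=np.array([[2.0, 0.0, 0.0, 1.0]])
        )
        poly = efa.efa_inverse(cs, 256)
        assert poly[:, 0].max() == pytest.approx(2.0, abs=1e-12)
        assert poly[:, 1].max() == pytest.approx(1.0, abs=1e-6)
        # on-ellipse residual
        assert np.max(np.abs((poly[:, 0] / 2) ** 2 + poly[:, 1] ** 2 - 1)) < 1e-9

    def test_round_trip_error_nonincreasing_in_harmonics(self, cephalon_outline):
        pts = cephalon_outline.points
        cs = efa.efa_forward(pts, 64)
        errs = []
        for N in range(1, 65):
            rec = efa.efa_inverse(cs, 128, n_harmonics=N)
            errs.append(np.sqrt(np.mean((rec - pts) ** 2)))
        assert np.all(np.diff(errs) <= 1e-10)

    def test_round_trip_at_maximal_harmonics_128(self, smooth_blob):
        # protocol-scale round trip: truncation tail of the 128-vertex
        # piecewise-linear contour keeps this near 1e-4 relative
        cs = efa.efa_forward(smooth_blob, 64)
        rec = efa.efa_inverse(cs, 128)
        diam = np.linalg.norm(smooth_blob.max(0) - smooth_blob.min(0))
        assert np.sqrt(np.mean((rec - smooth_blob) ** 2)) / diam < 1e-3


class TestNormalization:
    def _norm(self, pts, N=13):
        return efa.normalize_coefficients(efa.efa_forward(pts, N))

    def test_rotation_invariance(self, cephalon_outline):
        pts = cephalon_outline.points
        R = np.array(
            [[np.cos(np.radians(37)), -np.sin(np.radians(37))],
             [np.sin(np.radians(37)), np.cos(np.radians(37))]]
        )
        np.testing.assert_allclose(
            self._norm(pts @ R.T).harmonics, self._norm(pts).harmonics, atol=1e-8
        )

    def test_scale_invariance_and_divisor(self, cephalon_outline):
        pts = cephalon_outline.points
        base, scaled = self._norm(pts), self._norm(pts * 2.0)
        np.testing.assert_allclose(scaled.harmonics, base.harmonics, atol=1e-8)
        assert scaled.normalization.size_divisor / base.normalization.size_divisor == (
            pytest.approx(2.0, rel=1e-9)
        )

    def test_start_point_orbit_collapses(self, cephalon_outline):
        # stronger than a single 17-step shift: every discrete start position
        # must normalize to the same coefficients (exhaustive phase search)
        pts = cephalon_outline.points
        base = self._norm(pts).harmonics
        for roll in (1, 17, 33, 64, 100, 127):
            shifted = self._norm(np.roll(pts, roll, axis=0)).harmonics
            np.testing.assert_allclose(shifted, base, atol=1e-6)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_similarity_transform_invariance_property(self, seed):
        from trilomorph.synthetic import CephalonParams, generate_cephalon

        rng = np.random.default_rng(seed)
        pts = generate_cephalon(
            CephalonParams(), rng=np.random.default_rng(seed % 1000)
        ).points
        angle = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.2, 5.0)
        shift = rng.uniform(-50, 50, 2)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        transformed = pts @ R.T * scale + shift
        np.testing.assert_allclose(
            self._norm(transformed).harmonics, self._norm(pts).harmonics, atol=1e-7
        )

    def test_first_harmonic_standardized(self, cephalon_outline):
        h1 = self._norm(cephalon_outline.points).harmonics[0]
        assert h1[0] == pytest.approx(1.0, abs=1e-12)  # unit semi-major along +x
        assert abs(h1[2]) < 1e-9

    def test_double_normalization_rejected(self, cephalon_outline):
        n = self._norm(cephalon_outline.points)
        with pytest.raises(ValueError, match="already normalized"):
            efa.normalize_coefficients(n)

    def test_degenerate_first_harmonic_rejected(self):
        cs = efa.CoefficientSet(
            specimen_id="d", harmonics=np.array([[0.0, 0, 0, 0], [0.1, 0, 0, 0.1]])
        )
        with pytest.raises(efa.DegenerateHarmonicError):
            efa.normalize_coefficients(cs)


class TestPowerAndSelection:
    def test_hand_computed_power(self):
        cs = efa.CoefficientSet(specimen_id="p", harmonics=np.array([[2.0, 0, 0, 1.0]]))
        assert efa.harmonic_power(cs).power[0] == pytest.approx(2.5)

    def test_cumulative_fraction_ends_at_one(self, cephalon_outline):
        prof = efa.harmonic_power(efa.efa_forward(cephalon_outline.points, 32))
        assert prof.cumulative_fraction[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(prof.cumulative_fraction) >= -1e-15)

    def test_total_power_rotation_invariant(self, cephalon_outline):
        pts = cephalon_outline.points
        R = np.array([[0, -1], [1, 0]], float)
        p1 = efa.harmonic_power(efa.efa_forward(pts, 20)).power.sum()
        p2 = efa.harmonic_power(efa.efa_forward(pts @ R.T, 20)).power.sum()
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_pure_ellipses_select_one_harmonic(self):
        # pure single-harmonic spectra: all power in the first harmonic
        dataset = [
            efa.CoefficientSet(
                specimen_id=f"e{a}", harmonics=np.vstack([[a, 0, 0, 1.0], np.zeros((7, 4))])
            )
            for a in (1.5, 2.0, 3.0)
        ]
        assert efa.select_harmonics(dataset, threshold=0.999) == 1

    def test_constructed_spectrum_selects_five(self):
        # mean cumulative power: 0.9985 at N=4, 0.9992 at N=5
        powers = [0.99, 0.005, 0.002, 0.0015, 0.0007, 0.0008]
        harmonics = np.zeros((6, 4))
        harmonics[:, 0] = np.sqrt(2 * np.array(powers))
        dataset = [efa.CoefficientSet(specimen_id=f"s{i}", harmonics=harmonics) for i in range(3)]
        assert efa.select_harmonics(dataset, threshold=0.999) == 5

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            efa.select_harmonics([], threshold=0.999)


class TestMeanShape:
    def test_identical_members_reproduce_member(self, cephalon_outline):
        cs = efa.efa_forward(cephalon_outline.points, 16)
        single = efa.efa_inverse(cs, 128, include_dc=True)
        mean = efa.mean_shape([cs, cs, cs], n_points=128, include_dc=True)
        np.testing.assert_allclose(mean, single, atol=1e-12)

    def test_two_ellipse_sets_average_coefficientwise(self):
        c1 = efa.CoefficientSet(specimen_id="a", harmonics=np.array([[2.0, 0, 0, 1.0]]))
        c2 = efa.CoefficientSet(specimen_id="b", harmonics=np.array([[4.0, 0, 0, 3.0]]))
        mean = efa.mean_shape([c1, c2], n_points=512)
        assert mean[:, 0].max() == pytest.approx(3.0, abs=1e-9)
        assert mean[:, 1].max() == pytest.approx(2.0, abs=1e-6)

    def test_singleton_group(self, cephalon_outline):
        cs = efa.efa_forward(cephalon_outline.points, 8)
        np.testing.assert_allclose(
            efa.mean_shape([cs], n_points=64, include_dc=True),
            efa.efa_inverse(cs, 64, include_dc=True),
        )

    def test_mixed_harmonic_counts_rejected(self, cephalon_outline):
        c1 = efa.efa_forward(cephalon_outline.points, 8)
        c2 = efa.efa_forward(cephalon_outline.points, 9)
        with pytest.raises(ValueError, match="[Mm]ixed"):
            efa.mean_shape([c1, c2])


class TestCoefficientMatrix:
    def test_layout_and_ids(self, cephalon_outline):
        cs = efa.efa_forward(cephalon_outline.points, 3)
        cs.specimen_id = "spec7"
        df = efa.coefficient_matrix([cs])
        assert list(df.columns) == [
            "a1", "b1", "c1", "d1", "a2", "b2", "c2", "d2", "a3", "b3", "c3", "d3",
        ]
        assert df.index[0] == "spec7"
        np.testing.assert_array_equal(df.to_numpy()[0], cs.harmonics.ravel())
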