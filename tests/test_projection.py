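"""Hindcast, density-dependent projection and cover conversion."""

import math

import numpy as np
import pytest

import coraldemog as cd


class TestProjectLinear:
    def test_identity_matrix_constant_series(self):
        n0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        series = cd.project_linear(np.eye(5), n0, 4)
        assert np.all(series == n0)

    def test_zero_matrix_isolates_recruits(self):
        spec = cd.RecruitmentSpec.deterministic((5, 0, 0, 3, 0))
        series = cd.project_linear(np.zeros((5, 5)), np.zeros(5), 5, spec)
        np.testing.assert_array_equal(series[1], [5, 0, 0, 0, 0])
        np.testing.assert_array_equal(series[2], 0.0)
        np.testing.assert_array_equal(series[3], 0.0)
        np.testing.assert_array_equal(series[4], [3, 0, 0, 0, 0])

    def test_single_step_matches_hand_product(self, true_matrix):
        n0 = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
        series = cd.project_linear(true_matrix, n0, 1)
        expected = [sum(true_matrix.values[i, j] * n0[j] for j in range(5))
                    for i in range(5)]
        np.testing.assert_allclose(series[1], expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cd.project_linear(np.eye(5), np.ones(4), 3)


class TestHindcastFit:
    def test_perfect_prediction_gives_r2_of_one(self):
        obs = np.arange(10.0).reshape(2, 5)
        fit = cd.hindcast_fit(obs, obs)
        assert fit.r_squared == 1.0

    def test_grand_mean_prediction_gives_r2_of_zero(self):
        obs = np.arange(10.0).reshape(2, 5)
        fit = cd.hindcast_fit(np.full_like(obs, obs.mean()), obs)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_toy_case_matches_hand_arithmetic(self):
        obs = np.array([[1.0, 2.0], [3.0, 4.0]])
        pred = np.array([[1.5, 2.0], [2.0, 5.0]])
        sse = 0.25 + 0.0 + 1.0 + 1.0
        sst = sum((v - 2.5) ** 2 for v in (1, 2, 3, 4))
        fit = cd.hindcast_fit(pred, obs)
        assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_constant_observations_are_an_error(self):
        obs = np.full((2, 5), 3.0)
        with pytest.raises(ValueError):
            cd.hindcast_fit(obs + 0.1, obs)


class TestRickerFactors:
    def test_zero_b_means_no_inhibition(self):
        dd = cd.DensityDependence(b=(0.0,) * 5)
        np.testing.assert_array_equal(
            cd.ricker_factors(np.full(5, 1e6), dd), 1.0)

    def test_closed_form_value(self):
        dd = cd.DensityDependence()
        f = cd.ricker_factors(np.array([0, 0, 1000.0, 0, 0]), dd)
        assert f[2] == pytest.approx(math.exp(-1.0), abs=1e-9)

    def test_monotone_nonincreasing_in_abundance(self):
        dd = cd.DensityDependence()
        lo = cd.ricker_factors(np.full(5, 10.0), dd)
        hi = cd.ricker_factors(np.full(5, 100.0), dd)
        assert np.all(hi <= lo)
        assert np.all((lo > 0) & (lo <= 1))


class TestProjectDensityDependent:
    def test_density_free_limit_equals_linear_bitwise(self, decomp):
        n0 = np.array([50.0, 20.0, 10.0, 5.0, 2.0])
        spec = cd.RecruitmentSpec.deterministic((5, 0, 0, 3, 0))
        dd = cd.DensityDependence(b=(0.0,) * 5)
        dd_series = cd.project_density_dependent(decomp, dd, n0, 50, spec,
                                                 seed=0)
        lin_series = cd.project_linear(decomp.S + decomp.R, n0, 50, spec)
        assert np.array_equal(dd_series, lin_series)

    def test_subcritical_survival_decays_to_zero(self, structure):
        S = np.diag([0.4, 0.4, 0.4, 0.4, 0.4])
        d = cd.MatrixDecomposition(S=S, R=np.zeros((5, 5)),
                                   structure=structure)
        dd = cd.DensityDependence()
        series = cd.project_density_dependent(
            d, dd, np.full(5, 100.0), 100,
            cd.RecruitmentSpec.deterministic(()), seed=0)
        assert np.all(series[-1] < 1e-20)

    def test_defaults_stay_bounded_and_nonnegative(self, decomp):
        # imported recruitment N(25, 25) truncated at zero, b = 0.001 on the
        # three largest classes: the 100-year trajectory must neither
        # diverge nor go negative
        series = cd.project_density_dependent(
            decomp, cd.DensityDependence(), np.full(5, 20.0), 100,
            cd.RecruitmentSpec(), seed=11)
        assert np.all(series >= 0)
        assert np.all(np.isfinite(series))
        assert series.max() < 1e6

    def test_seed_reproducibility(self, decomp):
        args = (decomp, cd.DensityDependence(), np.full(5, 20.0), 100,
                cd.RecruitmentSpec())
        a = cd.project_density_dependent(*args, seed=21)
        b = cd.project_density_dependent(*args, seed=21)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("mode", ["fertility_only", "inflow", "outflow"])
    def test_all_modes_preserve_nonnegativity(self, decomp, mode):
        dd = cd.DensityDependence(b=(0.01,) * 5, mode=mode)
        series = cd.project_density_dependent(
            decomp, dd, np.full(5, 50.0), 100, cd.RecruitmentSpec(), seed=4)
        assert np.all(series >= 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cd.DensityDependence(mode="sideways")

    def test_eigen_limit_growth_factor(self, structure):
        # no recruitment, no density dependence: the per-step growth factor
        # converges to the dominant eigenvalue of S + R
        m = cd.generate_true_matrix(structure, 0.95, seed=5,
                                    fertility_range=(0.5, 1.0))
        d = cd.decompose(m)
        dd = cd.DensityDependence(b=(0.0,) * 5)
        series = cd.project_density_dependent(
            d, dd, np.full(5, 10.0), 200,
            cd.RecruitmentSpec.deterministic(()), seed=0)
        growth = series[-1].sum() / series[-2].sum()
        v = np.ones(5)
        for _ in range(5000):
            w = (d.S + d.R) @ v
            v = w / np.linalg.norm(w)
        lam = float(v @ (d.S + d.R) @ v)
        assert growth == pytest.approx(lam, abs=1e-6)


class TestCover:
    def test_zero_abundance_zero_cover(self, scheme):
        res = cd.cover_from_vector(np.zeros(5), scheme)
        assert res.total_pct == 0.0

    def test_single_large_colony_closed_form(self, scheme):
        # one 50 cm colony over 300 m2: 100 * pi * 0.25^2 / 300 ~ 0.06545 %
        n = np.array([0, 0, 0, 0, 1.0])
        res = cd.cover_from_vector(n, scheme, 300.0)
        assert res.total_pct == pytest.approx(100 * math.pi * 0.25 ** 2 / 300,
                                              abs=1e-9)
        assert res.total_pct == pytest.approx(0.06545, abs=1e-5)

    def test_linearity_in_abundance(self, scheme):
        n = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        a = cd.cover_from_vector(n, scheme).total_pct
        b = cd.cover_from_vector(2 * n, scheme).total_pct
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_total_is_sum_of_classes(self, scheme):
        n = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        res = cd.cover_from_vector(n, scheme)
        assert res.total_pct == pytest.approx(res.per_class_pct.sum())

    def test_nonpositive_area_rejected(self, scheme):
        with pytest.raises(ValueError):
            cd.cover_from_vector(np.ones(5), scheme, 0.0)


class TestTimeToStability:
    def test_constant_series_settles_immediately(self):
        assert cd.time_to_stability(np.full(50, 4.2), 10, 0.01) == 0

    def test_exponential_growth_never_settles(self):
        series = 1.05 ** np.arange(100)
        assert cd.time_to_stability(series, 10, 1e-4) is None

    def test_logistic_plateau_detected_near_onset(self):
        t = np.arange(120.0)
        series = 30.0 / (1.0 + np.exp(-(t - 40.0) / 5.0))
        onset = cd.time_to_stability(series, 20, 0.02)
        # the curve is within 2% of its local mean once it flattens;
        # constructed plateau onset is near t = 62 (98% of carrying capacity)
        assert onset is not None
        expected = int(np.argmax(series >= 0.98 * 30.0))
        assert abs(onset - expected) <= 2
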