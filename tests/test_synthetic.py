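"""Ground-truth generator and survey emulation."""

import numpy as np
import pytest

import coraldemog as cd


class TestGenerateTrueMatrix:
    def test_stasis_only_structure_gives_diagonal(self):
        s = cd.LifeCycleStructure.stasis_only(5)
        m = cd.generate_true_matrix(s, 0.9, seed=0).values
        assert np.all(m[~np.eye(5, dtype=bool)] == 0)
        assert np.all(np.diag(m) > 0)

    def test_life_cycle_support_and_survival_cap(self, structure):
        cap = 0.8
        m = cd.generate_true_matrix(structure, cap, seed=3)
        allowed = structure.allowed_mask()
        assert np.all(m.values[~allowed] == 0)
        assert np.all(m.survival_column_sums() <= cap + 1e-12)
        fert = structure.role_mask(("fertility",))
        assert np.all(m.values[fert] >= 0)

    def test_same_seed_same_matrix(self, structure):
        a = cd.generate_true_matrix(structure, 0.95, seed=7).values
        b = cd.generate_true_matrix(structure, 0.95, seed=7).values
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self, structure):
        with pytest.raises(ValueError):
            cd.generate_true_matrix(structure, 1.5, seed=0)
        with pytest.raises(cd.StructureError):
            cd.generate_true_matrix("not a structure", 0.9, seed=0)


class TestSimulateSeries:
    def test_identity_matrix_keeps_series_constant(self):
        s = cd.LifeCycleStructure.stasis_only(5)
        m = cd.TransitionMatrix(values=np.eye(5), structure=s)
        truth = cd.GroundTruth(matrix=m, initial_vector=np.full(5, 10.0))
        series = cd.simulate_series(truth, 5)
        assert np.all(series == 10.0)

    def test_zero_matrix_isolates_recruit_sequence(self, structure):
        m = cd.TransitionMatrix(values=np.zeros((5, 5)), structure=structure)
        truth = cd.GroundTruth(
            matrix=m, initial_vector=np.zeros(5),
            recruitment=cd.RecruitmentSpec.deterministic((5, 0, 0, 3, 0)))
        series = cd.simulate_series(truth, 5)
        np.testing.assert_array_equal(series[1], [5, 0, 0, 0, 0])
        np.testing.assert_array_equal(series[2], np.zeros(5))
        np.testing.assert_array_equal(series[4], [3, 0, 0, 0, 0])

    def test_single_step_is_the_matrix_vector_product(self, true_matrix):
        n0 = np.array([4.0, 3.0, 2.0, 1.0, 0.5])
        series = cd.simulate_series(
            cd.GroundTruth(matrix=true_matrix, initial_vector=n0), 1)
        # brute-force dot product, entry by entry
        expected = [sum(true_matrix.values[i, j] * n0[j] for j in range(5))
                    for i in range(5)]
        np.testing.assert_allclose(series[1], expected, rtol=0, atol=1e-12)

    def test_negative_initial_vector_rejected(self, true_matrix):
        with pytest.raises(ValueError):
            cd.GroundTruth(matrix=true_matrix,
                           initial_vector=np.array([1, -1, 0, 0, 0.0]))

    def test_convergence_to_dominant_eigenpair(self, true_matrix):
        # with no recruitment the normalized vector approaches the dominant
        # eigenvector and the step growth factor the dominant eigenvalue
        truth = cd.GroundTruth(matrix=true_matrix,
                               initial_vector=np.full(5, 10.0))
        series = cd.simulate_series(truth, 200)
        growth = series[-1].sum() / series[-2].sum()
        # independent power iteration
        v = np.full(5, 1.0)
        for _ in range(2000):
            w = true_matrix.values @ v
            v = w / np.linalg.norm(w)
        lam = float(v @ true_matrix.values @ v)
        assert growth == pytest.approx(lam, abs=1e-6)
        direction = series[-1] / np.linalg.norm(series[-1])
        np.testing.assert_allclose(direction, v, atol=1e-6)


class TestEmulateSurvey:
    def test_identity_observation(self, true_matrix, scheme):
        truth = cd.GroundTruth(matrix=true_matrix,
                               initial_vector=np.full(5, 50.0))
        series = cd.simulate_series(truth, 4)
        obs = cd.ObservationModel(
            transects_per_year={y: 6 for y in range(2010, 2015)},
            missing_years=frozenset(), sc1_detection_prob=1.0)
        survey = cd.emulate_survey(series, obs, scheme, seed=0,
                                   years=range(2010, 2015))
        got = survey[scheme.column_names()].to_numpy()
        np.testing.assert_array_equal(got, np.round(series))

    def test_missing_years_absent(self, true_matrix, scheme):
        truth = cd.GroundTruth(matrix=true_matrix,
                               initial_vector=np.full(5, 50.0))
        series = cd.simulate_series(truth, 4)
        obs = cd.ObservationModel(
            transects_per_year={y: 6 for y in range(2010, 2015)},
            missing_years=frozenset({2011, 2012}))
        survey = cd.emulate_survey(series, obs, scheme, seed=0,
                                   years=range(2010, 2015))
        assert set(survey["year"]) == {2010, 2013, 2014}

    def test_sc1_binomial_thinning_expectation(self, scheme):
        # mean observed SC1 over many replicate draws should match half the
        # true SC1 within 3 standard errors of the binomial mean
        true_sc1 = 200.0
        reps = 10_000
        series = np.tile([true_sc1, 10.0, 10.0, 10.0, 10.0], (reps, 1))
        obs = cd.ObservationModel(
            transects_per_year={y: 6 for y in range(reps)},
            missing_years=frozenset(), sc1_detection_prob=0.5)
        survey = cd.emulate_survey(series, obs, scheme, seed=99,
                                   years=range(reps))
        draws = survey["sc1"].to_numpy()
        p = 0.5
        se = np.sqrt(true_sc1 * p * (1 - p) / reps)
        assert abs(draws.mean() - p * true_sc1) < 3 * se

    def test_same_seed_same_survey(self, true_matrix, scheme):
        truth = cd.GroundTruth(matrix=true_matrix,
                               initial_vector=np.full(5, 80.0))
        series = cd.simulate_series(truth, 4)
        obs = cd.ObservationModel(
            transects_per_year={y: 6 for y in range(2010, 2015)},
            missing_years=frozenset(), count_noise="poisson")
        a = cd.emulate_survey(series, obs, scheme, seed=5, years=range(2010, 2015))
        b = cd.emulate_survey(series, obs, scheme, seed=5, years=range(2010, 2015))
        assert a.equals(b)

    def test_effort_share_scaling(self, scheme):
        series = np.array([[0.0, 12.0, 24.0, 6.0, 6.0]])
        obs = cd.ObservationModel(transects_per_year={2010: 3},
                                  missing_years=frozenset(),
                                  reference_transects=6)
        survey = cd.emulate_survey(series, obs, scheme, seed=0, years=[2010])
        np.testing.assert_array_equal(
            survey[scheme.column_names()].to_numpy()[0], [0, 6, 12, 3, 3])
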