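"""Factor loadings, measurement noise, and percentile-rank predictors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from compsel import (
    FactorLoadings,
    GroundTruthScenario,
    InvalidValueError,
    SimulationConfig,
    add_measurement_noise,
    build_predictors,
    expected_percentile_correlation,
    linear_combination,
    percentile_transform,
    sample_latents,
    validate_loadings,
)
from compsel.errors import ConfigurationError
from compsel.population import LatentMatrix
from compsel.rng import RngStreams, substream

EXAMPLE_LATENTS = LatentMatrix(np.array([[-0.158, -0.158, 0.282, 0.282]]))


class TestLinearCombination:
    def test_correlated_loading_worked_example(self):
        raw = linear_combination(EXAMPLE_LATENTS, FactorLoadings.correlated())
        test, grades, letters, statement = raw[0]
        assert test == pytest.approx(-0.158, abs=1e-3)
        assert grades == pytest.approx(-0.088, abs=1e-3)
        assert letters == pytest.approx(0.299, abs=1e-3)
        assert statement == pytest.approx(0.282, abs=1e-3)

    def test_identity_loadings_pass_through(self, rng):
        lat = LatentMatrix(rng.standard_normal((20, 4)))
        raw = linear_combination(lat, FactorLoadings.identity())
        np.testing.assert_allclose(raw, lat.values)

    def test_dimension_mismatch(self, rng):
        lat = LatentMatrix(rng.standard_normal((5, 3)))
        with pytest.raises(InvalidValueError):
            linear_combination(lat, FactorLoadings.identity())


class TestMeasurementNoise:
    def test_zero_noise_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(add_measurement_noise(x, 0.0, rng), x)

    def test_unit_noise_doubles_variance(self):
        n = 200_000
        x = substream(1, "sig").standard_normal(n)
        noisy = add_measurement_noise(x, 1.0, substream(1, "noise"))
        assert noisy.var() == pytest.approx(2.0, abs=3 * 2 * np.sqrt(2 / n))

    def test_seeded_repeatability(self):
        x = np.linspace(-2, 2, 50)
        a = add_measurement_noise(x, 1.0, substream(7, "noise"))
        b = add_measurement_noise(x, 1.0, substream(7, "noise"))
        np.testing.assert_array_equal(a, b)

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(InvalidValueError):
            add_measurement_noise(np.zeros(3), -0.5, rng)


class TestPercentileTransform:
    def test_rank_arithmetic(self):
        np.testing.assert_allclose(
            percentile_transform(np.array([3.1, -2.0, 0.5])),
            [100.0, 100 / 3, 200 / 3],
        )

    def test_sorted_input_gives_uniform_grid(self):
        n = 7
        out = percentile_transform(np.arange(n, dtype=float))
        np.testing.assert_allclose(out, 100 * np.arange(1, n + 1) / n)

    def test_normal_input_is_uniform(self):
        n = 100_000
        x = substream(2, "x").standard_normal(n)
        pct = percentile_transform(x)
        ks = stats.kstest(pct, stats.uniform(0, 100).cdf).statistic
        assert ks < 0.01

    def test_empty_rejected(self):
        with pytest.raises(InvalidValueError):
            percentile_transform(np.array([]))

    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    def test_invariant_under_monotone_transforms(self, values):
        """Percentiles depend only on the ordering of the input."""
        x = np.asarray(values, dtype=float) / 7.0
        np.testing.assert_array_equal(
            percentile_transform(x), percentile_transform(np.exp(x / 200.0))
        )


class TestScenarios:
    def test_named_scenarios(self):
        inv = GroundTruthScenario.from_name("invalid_test")
        assert inv.invalid_predictors == {"Test"}
        np.testing.assert_array_equal(inv.loadings.matrix, np.eye(4))
        ow = GroundTruthScenario.from_name("valid_uncorrelated_overweighted")
        assert ow.default_test_weight == 1.3
        corr = GroundTruthScenario.from_name("valid_correlated")
        assert corr.loadings.row("Grades")[0] == 0.58
        with pytest.raises(ConfigurationError):
            GroundTruthScenario.from_name("nope")


class TestBuildPredictors:
    def test_invalid_test_independent_of_latents(self, invalid_test_cohort):
        tol = 3 / np.sqrt(invalid_test_cohort.n)
        test_pct = invalid_test_cohort.panel.column("Test")
        for j in range(4):
            r = stats.pearsonr(test_pct, invalid_test_cohort.latents.values[:, j])
            assert abs(r.statistic) < tol
        # ... and of the completion outcome in the full population
        r = stats.pearsonr(test_pct, invalid_test_cohort.outcomes.outcome)
        assert abs(r.statistic) < tol

    def test_columns_marginally_uniform(self, valid_correlated_cohort):
        n = valid_correlated_cohort.n
        for name in valid_correlated_cohort.panel.predictor_names:
            pct = valid_correlated_cohort.panel.column(name)
            ks = stats.kstest(pct, stats.uniform(0, 100).cdf).statistic
            assert ks < 3 / np.sqrt(n)

    def test_uncorrelated_scenario_off_diagonals_vanish(
        self, valid_uncorrelated_cohort
    ):
        pct = valid_uncorrelated_cohort.panel.percentiles
        corr = np.corrcoef(pct.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(valid_uncorrelated_cohort.n)

    def test_correlated_scenario_matches_analytic_rank_correlation(
        self, valid_correlated_cohort
    ):
        """MC percentile correlations track (6/pi)*arcsin(rho/2) for all pairs."""
        panel = valid_correlated_cohort.panel
        loadings = valid_correlated_cohort.scenario.loadings
        tol = 3 / np.sqrt(valid_correlated_cohort.n)
        for i, p in enumerate(panel.predictor_names):
            for q in panel.predictor_names[i + 1 :]:
                expected, ok = expected_percentile_correlation(loadings, 1.0, p, q)
                assert ok
                mc = stats.pearsonr(panel.column(p), panel.column(q)).statistic
                assert mc == pytest.approx(expected, abs=tol)

    def test_no_test_predictors_identical_across_test_validity(self, mid_config):
        """Swapping a valid Test for an invalid one leaves the other columns
        bit-identical thanks to named noise substreams."""
        from compsel.cohort import simulate_cohort

        a = simulate_cohort(GroundTruthScenario.from_name("invalid_test"), mid_config)
        b = simulate_cohort(
            GroundTruthScenario.from_name("valid_uncorrelated"), mid_config
        )
        for name in ("Grades", "Letters", "Statement"):
            np.testing.assert_array_equal(a.panel.column(name), b.panel.column(name))
        assert not np.array_equal(a.panel.column("Test"), b.panel.column("Test"))


class TestLoadingValidation:
    def test_identity_passes(self):
        report = validate_loadings(FactorLoadings.identity())
        assert all(v["ok"] for v in report.values())

    def test_printed_correlated_rows_pass(self):
        report = validate_loadings(FactorLoadings.correlated())
        assert report["Grades"]["sum_sq"] == pytest.approx(1.0086)
        assert all(v["ok"] for v in report.values())

    def test_overweight_row_flagged(self):
        bad = FactorLoadings(
            np.array([[1, 1, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        )
        report = validate_loadings(bad)
        assert not report["Test"]["ok"]
        assert report["Test"]["sum_sq"] == 2.0


class TestExpectedPercentileCorrelation:
    def test_correlated_test_grades(self):
        r, ok = expected_percentile_correlation(
            FactorLoadings.correlated(), 1.0, "Test", "Grades"
        )
        assert ok
        assert r == pytest.approx(0.277, abs=0.002)

    def test_identity_pairs_uncorrelated(self):
        r, ok = expected_percentile_correlation(
            FactorLoadings.identity(), 1.0, "Test", "Grades"
        )
        assert ok and r == 0.0

    def test_self_correlation_without_noise(self):
        r, _ = expected_percentile_correlation(
            FactorLoadings.identity(), 0.0, "Test", "Test"
        )
        assert r == pytest.approx(1.0)

    def test_invalid_predictor_flagged(self):
        r, ok = expected_percentile_correlation(
            FactorLoadings.identity(), 1.0, "Test", "Grades",
            invalid_predictors=frozenset({"Test"}),
        )
        assert (r, ok) == (0.0, False)
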