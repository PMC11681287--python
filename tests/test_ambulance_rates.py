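"""Ambulance-use rate estimators: naive, weighted naive, binomial bootstrap."""

import numpy as np
import pandas as pd
import pytest
from fractions import Fraction
from scipy import stats

from emsdemand import (
    DegenerateDistributionError,
    ConfigurationError,
    EstimationError,
    aggregate_survey,
    compare_to_reference,
    monte_carlo_rate,
    naive_rate,
    pooled_rate,
    weighted_naive_rate,
)
from emsdemand.ambulance_rates import AmbulanceRateEstimate

from conftest import make_counts


class TestAggregation:
    def test_counts_conserve_survey_totals(self, default_survey):
        counts = aggregate_survey(default_survey)
        assert counts["n_total"].sum() == len(default_survey)
        assert counts["n_ambulance"].sum() == default_survey["used_ambulance"].sum()
        assert (counts["n_ambulance"] <= counts["n_total"]).all()

    def test_empty_survey_gives_empty_counts(self):
        counts = aggregate_survey(pd.DataFrame(columns=["neighborhood_id", "used_ambulance"]))
        assert len(counts) == 0

    def test_single_area_direct_count(self):
        survey = pd.DataFrame(
            {"patient_id": [1, 2, 3], "neighborhood_id": ["K1"] * 3,
             "period": ["day"] * 3, "used_ambulance": [0, 1, 0]}
        )
        counts = aggregate_survey(survey)
        assert counts.iloc[0]["n_total"] == 3 and counts.iloc[0]["n_ambulance"] == 1


class TestPointEstimators:
    def test_pooled_rate_examples(self):
        assert round(pooled_rate(make_counts([("K1", 1964, 183)])), 3) == 0.093
        assert pooled_rate(make_counts([("K1", 4, 4)])) == 1.0
        assert pooled_rate(make_counts([("K1", 2, 1), ("K2", 2, 1)])) == 0.5

    def test_naive_rate_mean_of_proportions(self):
        assert naive_rate(make_counts([("K1", 10, 0), ("K2", 10, 2)])).delta == pytest.approx(0.1)
        assert naive_rate(make_counts([("K1", 5, 1), ("K2", 20, 4)])).delta == pytest.approx(0.2)

    def test_naive_rate_matches_exact_fraction_oracle(self, rng):
        """On a 50-row random fixture the naive mean equals an exact
        rational-arithmetic recomputation."""
        n = rng.integers(1, 40, size=50)
        k = rng.binomial(n, 0.1)
        counts = make_counts(list(zip([f"K{i}" for i in range(50)], n, k)))
        exact = sum(Fraction(int(ki), int(ni)) for ni, ki in zip(n, k)) / 50
        assert naive_rate(counts).delta == pytest.approx(float(exact), abs=1e-14)

    def test_naive_excludes_zero_total_rows(self):
        counts = make_counts([("K1", 0, 0), ("K2", 10, 1)])
        assert naive_rate(counts).delta == pytest.approx(0.1)
        with pytest.raises(EstimationError):
            naive_rate(make_counts([("K1", 0, 0)]))

    def test_weighted_equals_naive_under_uniform_weights(self):
        reg = pd.DataFrame(
            {"id": ["K1", "K2"], "district": "D1", "municipality": "M",
             "pop_night": [900, 900], "pop_day": [1_000, 1_000]}
        )
        counts = make_counts([("K1", 10, 3), ("K2", 5, 1)])
        assert weighted_naive_rate(counts, reg).delta == pytest.approx(
            naive_rate(counts).delta
        )

    def test_weighted_rate_matches_hand_rolled_oracle(self, rng):
        ids = [f"K{i}" for i in range(20)]
        pops = rng.integers(1_000, 90_000, size=20)
        n = rng.integers(1, 30, size=20)
        k = rng.binomial(n, 0.12)
        reg = pd.DataFrame({"id": ids, "district": "D1", "municipality": "M",
                            "pop_night": pops, "pop_day": pops})
        counts = make_counts(list(zip(ids, n, k)))
        oracle = sum(p * ki / ni for p, ni, ki in zip(pops, n, k)) / pops.sum()
        assert weighted_naive_rate(counts, reg).delta == pytest.approx(oracle)
        single = weighted_naive_rate(make_counts([("K3", 8, 2)]), reg)
        assert single.delta == pytest.approx(0.25)

    def test_weighted_rate_missing_population_rejected(self):
        reg = pd.DataFrame({"id": ["K1"], "district": "D1", "municipality": "M",
                            "pop_night": [10], "pop_day": [10]})
        from emsdemand import InputError
        with pytest.raises(InputError):
            weighted_naive_rate(make_counts([("K9", 5, 1)]), reg)


class TestMonteCarlo:
    def test_degenerate_proportions(self):
        zero = monte_carlo_rate(make_counts([("K1", 10, 0), ("K2", 5, 0)]), 100, seed=0)
        assert zero.delta == 0.0 and zero.ci_low == zero.ci_high == 0.0
        one = monte_carlo_rate(make_counts([("K1", 10, 10)]), 100, seed=0)
        assert one.delta == 1.0

    def test_bootstrap_unbiasedness_against_naive(self, rng):
        """The binomial bootstrap mean is unbiased for the observed naive
        mean: at 10,000 replicates the two agree within 3 Monte Carlo SEs."""
        n = np.full(40, 60)
        k = rng.binomial(n, 0.093)
        counts = make_counts(list(zip([f"K{i}" for i in range(40)], n, k)))
        est = monte_carlo_rate(counts, n_replicates=10_000, seed=5)
        se = np.std(est.replicate_means, ddof=1) / np.sqrt(est.n_replicates)
        assert abs(est.delta - naive_rate(counts).delta) < 3 * se
        assert est.ci_low <= est.delta <= est.ci_high

    def test_seed_determinism(self):
        counts = make_counts([("K1", 30, 3), ("K2", 12, 1), ("K3", 7, 2)])
        a = monte_carlo_rate(counts, 500, seed=13)
        b = monte_carlo_rate(counts, 500, seed=13)
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    def test_ci_coverage_at_known_rate(self, rng):
        """Across 200 independent synthetic surveys, the normal-approximation
        95% CI covers the bootstrap's expected value (the naive mean of that
        survey) at the nominal rate within 5 percentage points."""
        hits = 0
        for s in range(200):
            n = np.full(20, 50)
            k = rng.binomial(n, 0.2)
            counts = make_counts(list(zip([f"K{i}" for i in range(20)], n, k)))
            est = monte_carlo_rate(counts, n_replicates=200, seed=s)
            if est.ci_low <= naive_rate(counts).delta <= est.ci_high:
                hits += 1
        assert abs(hits / 200 - 0.95) <= 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ConfigurationError):
            monte_carlo_rate(make_counts([("K1", 5, 1)]), n_replicates=1, seed=0)


class TestComparison:
    def _estimate(self, values):
        arr = np.asarray(values, dtype=float)
        return AmbulanceRateEstimate(
            method="simulation", delta=float(arr.mean()),
            replicate_means=arr, n_replicates=len(arr), seed=0,
        )

    def test_symmetric_replicates_do_not_reject(self, rng):
        noise = rng.normal(0, 0.01, size=500)
        values = 0.07 + np.concatenate([noise, -noise])
        res = compare_to_reference(self._estimate(values), 0.07)
        assert abs(res.t_statistic) < 1e-8 and res.p_value > 0.999

    def test_large_shift_rejects(self, rng):
        values = 0.07 + rng.normal(0, 0.001, size=200) + 0.01
        res = compare_to_reference(self._estimate(values), 0.07)
        assert res.p_value < 0.001 and res.significant

    def test_matches_textbook_formula(self, rng):
        """t and p equal the closed form t = (xbar - mu) / (s / sqrt(n))."""
        values = rng.normal(0.08, 0.005, size=100)
        mu = 0.081
        res = compare_to_reference(self._estimate(values), mu)
        t_oracle = (values.mean() - mu) / (values.std(ddof=1) / np.sqrt(100))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=99)
        assert res.t_statistic == pytest.approx(t_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_zero_variance_reported_not_nan(self):
        with pytest.raises(DegenerateDistributionError):
            compare_to_reference(self._estimate([0.07] * 50), 0.07)
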