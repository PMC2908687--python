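"""Founder-cell estimators: moment identities, distribution fit, reports."""

import numpy as np
import pandas as pd
import pytest

from epifounder import (
    CohortConfig,
    binomial_score_pmf,
    fit_n_distribution,
    founder_report,
    founder_table,
    moment_n,
    sample_variance,
    simulate_cohort,
    simulate_founder_scores,
)
from epifounder.founder_estimation import DegenerateDistributionError


class TestSampleVariance:
    def test_constant_and_two_point(self):
        assert sample_variance([0.0, 0.0, 0.0]) == 0.0
        assert sample_variance([0.0, 1.0], ddof=1) == pytest.approx(0.5)

    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            sample_variance([1.0])

    def test_matches_binomial_model_variance(self, rng):
        # Monte-Carlo oracle: scores k/N, k~Bin(10, 0.1) have variance pq/N
        scores = rng.binomial(10, 0.1, size=10_000) / 10
        assert sample_variance(scores) == pytest.approx(0.009, abs=0.0005)


class TestMomentN:
    def test_round_trip_of_variance_relation(self):
        assert moment_n(0.5, 0.25 / 12) == pytest.approx(12.0)

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5])
    @pytest.mark.parametrize("n", [1, 2, 7, 33, 100])
    def test_inverts_model_variance_exactly(self, n, p):
        dist = binomial_score_pmf(n, p)
        assert moment_n(p, dist.variance) == pytest.approx(n, rel=1e-9)

    def test_strictly_decreasing_in_variance(self):
        variances = np.linspace(0.001, 0.25, 50)
        estimates = [moment_n(0.5, v) for v in variances]
        assert all(a > b for a, b in zip(estimates, estimates[1:]))

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDistributionError, match="unbounded"):
            moment_n(0.5, 0.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            moment_n(p, 0.01)


class TestBinomialScorePmf:
    def test_single_founder_is_bernoulli(self):
        dist = binomial_score_pmf(1, 0.5)
        assert dist.support.tolist() == [0.0, 1.0]
        assert dist.mass.tolist() == pytest.approx([0.5, 0.5])

    def test_two_founders(self):
        dist = binomial_score_pmf(2, 0.5)
        assert dist.mass.tolist() == pytest.approx([0.25, 0.5, 0.25])

    @pytest.mark.parametrize("n", range(1, 101))
    def test_normalization_and_moments(self, n):
        dist = binomial_score_pmf(n, 0.1)
        assert abs(dist.mass.sum() - 1.0) < 1e-12
        assert dist.mean == pytest.approx(0.1, abs=1e-12)
        assert dist.variance == pytest.approx(0.09 / n, rel=1e-9)


class TestFitNDistribution:
    def test_recovers_generating_n(self, rng):
        scores = rng.binomial(9, 0.5, size=5_000) / 9
        n_fit, _ = fit_n_distribution(scores, 0.5)
        assert n_fit == 9

    def test_recovery_within_sampling_error_small_p(self, rng):
        scores = rng.binomial(10, 0.1, size=10_000) / 10
        n_fit, _ = fit_n_distribution(scores, 0.1)
        assert n_fit in {9, 10, 11}

    @pytest.mark.parametrize("metric", ["chi2_binned", "ks"])
    def test_both_metrics_agree_on_clean_data(self, metric, rng):
        scores = rng.binomial(12, 0.5, size=5_000) / 12
        n_fit, d = fit_n_distribution(scores, 0.5, metric=metric)
        assert n_fit == 12
        assert d >= 0

    def test_consistent_with_moment_estimator(self, rng):
        for n_true in (5, 15):
            scores = rng.binomial(n_true, 0.5, size=5_000) / n_true
            n_fit, _ = fit_n_distribution(scores, 0.5)
            n_mom = moment_n(0.5, sample_variance(scores))
            assert abs(n_fit - round(n_mom)) <= 1

    def test_zero_variance_pins_to_grid_top(self):
        with pytest.warns(UserWarning, match="degenerate"):
            n_fit, d = fit_n_distribution([0.1] * 50, 0.1, n_max=40)
        assert n_fit == 40
        assert np.isnan(d)

    def test_scores_outside_unit_interval_excluded(self, rng, caplog):
        scores = np.concatenate([rng.binomial(8, 0.5, 1_000) / 8, [1.7, -0.2]])
        with caplog.at_level("WARNING"):
            n_fit, _ = fit_n_distribution(scores, 0.5)
        assert n_fit == 8
        assert "outside [0, 1]" in caplog.text

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_n_distribution([0.1, 0.5], 0.5)

    def test_noise_convolution_still_recovers(self, rng):
        scores = simulate_founder_scores(10, 0.5, 5_000, noise_sd=0.05, rng=rng)
        n_fit, _ = fit_n_distribution(scores, 0.5, noise_sd=0.05)
        assert abs(n_fit - 10) <= 1


class TestFounderReport:
    def test_recovers_group_founder_number_at_study_size(self, rng):
        # 54 females x 5 placenta sections, 11 founders, balanced X-inactivation
        rows = []
        for i in range(54):
            scores = simulate_founder_scores(11, 0.5, 5, rng=rng)
            for sec, value in enumerate(scores, start=1):
                rows.append((f"f{i}", "in_vivo", f"placenta_{sec}", "AR", "XI", value))
        ratios = pd.DataFrame(
            rows,
            columns=["individual_id", "group", "tissue", "locus", "score_kind", "value"],
        )
        est = founder_report(ratios, 0.5, "in_vivo", score_kind="XI")
        assert est.n_samples == 270
        assert abs(est.n_moment - 11) / 11 < 0.15

    def test_p_defaults_to_group_mean(self, default_cohort):
        ratios, _ = default_cohort
        est = founder_report(ratios, None, "in_vivo", score_kind="MP")
        assert est.p == pytest.approx(est.sample_mean)
        assert est.q == pytest.approx(1 - est.p)

    def test_zero_variance_error_propagates(self):
        ratios = pd.DataFrame(
            {
                "individual_id": [f"x{i}" for i in range(25)],
                "group": ["in_vivo"] * 25,
                "tissue": ["placenta_1"] * 25,
                "locus": ["IGF2_H19"] * 25,
                "score_kind": ["MP"] * 25,
                "value": [0.1] * 25,
            }
        )
        with pytest.raises(DegenerateDistributionError):
            founder_report(ratios, 0.1, "in_vivo", score_kind="MP")

    def test_no_matching_records_rejected(self, default_cohort):
        ratios, _ = default_cohort
        with pytest.raises(ValueError, match="no records"):
            founder_report(ratios, 0.5, "in_vivo", score_kind="PM")

    def test_table_has_one_row_per_assay_group(self, default_cohort):
        ratios, _ = default_cohort
        table = founder_table(ratios)
        assert set(zip(table["assay"], table["group"])) == {
            ("XI", "in_vitro"),
            ("XI", "in_vivo"),
            ("MP", "in_vitro"),
            ("MP", "in_vivo"),
        }
        assert (table["n_moment"] > 0).all()
        assert table["n_fit"].between(1, 100).all()


def test_in_vitro_group_shows_larger_variance_in_expectation():
    """Fewer founders -> larger score variance, visible at study scale."""
    ratios, _ = simulate_cohort(CohortConfig(seed=11))
    table = founder_table(ratios, assays=[("MP", 0.1)])
    by_group = table.set_index("group")
    assert (
        by_group.loc["in_vitro", "variance"] > by_group.loc["in_vivo", "variance"]
    )
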