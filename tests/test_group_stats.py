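"""Group comparisons: rank-sum, variance equality, summaries, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epifounder import (
    CohortConfig,
    ddct,
    fold_change_table,
    simulate_cohort,
    summarize_groups,
    variance_equality_test,
    wilcoxon_rank_sum,
)


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        # 2 of the C(6,3)=20 rank assignments are as extreme as W=6
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_symmetry_in_group_order(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        assert wilcoxon_rank_sum(a, b, "exact")[1] == pytest.approx(
            wilcoxon_rank_sum(b, a, "exact")[1]
        )
        assert wilcoxon_rank_sum(a, b, "normal_approx")[1] == pytest.approx(
            wilcoxon_rank_sum(b, a, "normal_approx")[1]
        )

    def test_exact_matches_independent_reference(self, rng):
        # cross-check enumeration against scipy's recursive exact method
        for _ in range(50):
            n1, n2 = rng.integers(2, 6, size=2)
            pooled = rng.choice(10_000, size=n1 + n2, replace=False).astype(float)
            a, b = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_rank_sum(a, b, mode="exact")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_with_ties_matches_permutation_sampler(self, rng):
        a, b = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(a, b, mode="exact")
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        mu = ranks.sum() * len(a) / len(pooled)
        w_obs = ranks[: len(a)].sum()
        hits = sum(
            abs(rng.permutation(ranks)[: len(a)].sum() - mu) >= abs(w_obs - mu) - 1e-9
            for _ in range(20_000)
        )
        assert p == pytest.approx(hits / 20_000, abs=0.02)

    def test_normal_approximation_tracks_exact(self, rng):
        deviations = []
        for _ in range(200):
            n1, n2 = rng.integers(3, 8, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), 1, n2)
            p_exact = wilcoxon_rank_sum(a, b, "exact")[1]
            p_norm = wilcoxon_rank_sum(a, b, "normal_approx")[1]
            deviations.append(abs(p_exact - p_norm))
        assert max(deviations) < 0.05

    def test_exact_mode_size_limit(self, rng):
        with pytest.raises(ValueError, match="exact mode limited"):
            wilcoxon_rank_sum(rng.normal(size=15), rng.normal(size=15), "exact")


class TestVarianceEqualityTest:
    def test_identical_samples_boundary(self, rng):
        a = rng.normal(0, 1, 20)
        stat, p = variance_equality_test(a, a)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            variance_equality_test([1.0] * 5, [2.0] * 5)

    @pytest.mark.parametrize("method", ["levene_median", "f_test"])
    def test_detects_threefold_spread(self, method):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(5_000 + seed)
            a = rng.normal(0, 1, 100)
            b = 3 * (a - a.mean()) + a.mean()
            _, p = variance_equality_test(a, b, method=method)
            detected += p < 0.05
        assert detected >= 95

    def test_f_test_is_two_sided(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0, 3, 50)
        _, p_ab = variance_equality_test(a, b, method="f_test")
        _, p_ba = variance_equality_test(b, a, method="f_test")
        assert p_ab == pytest.approx(p_ba)


class TestSummarizeGroups:
    def test_table_shape_and_totals(self, default_cohort):
        ratios, _ = default_cohort
        table = summarize_groups(ratios, "MP")
        assert set(table["tissue"]) == {"cord_blood", "cord", "placenta", "total"}
        assert len(table) == 8  # 4 tissue sets x 2 groups
        # total row pools every record of the group
        mp = ratios[ratios["score_kind"] == "MP"]
        for group in ("in_vitro", "in_vivo"):
            vals = mp.loc[mp["group"] == group, "value"]
            row = table[(table["tissue"] == "total") & (table["group"] == group)]
            assert row["n"].item() == len(vals)
            assert row["mean"].item() == pytest.approx(vals.mean())
            assert row["variance"].item() == pytest.approx(vals.var(ddof=1))
        assert table["p_means"].between(0, 1).all()
        assert table["p_variances"].between(0, 1).all()

    def test_single_group_has_no_pvalues(self, default_cohort):
        ratios, _ = default_cohort
        only_vivo = ratios[ratios["group"] == "in_vivo"]
        table = summarize_groups(only_vivo, "MP")
        assert table["p_means"].isna().all()
        assert (table["group"] == "in_vivo").all()

    def test_null_cohort_not_systematically_significant(self):
        # equal founders and sizes: location test should be quiet mostly
        rejections = 0
        for seed in range(20):
            config = CohortConfig(
                n_in_vitro=30, n_in_vivo=30,
                founders_in_vitro=10, founders_in_vivo=10, seed=8_000 + seed,
            )
            ratios, _ = simulate_cohort(config)
            table = summarize_groups(ratios, "MP")
            row = table[table["tissue"] == "total"].iloc[0]
            rejections += row["p_means"] < 0.05
        assert rejections <= 4


def _ct_table(dct_in_vitro, dct_in_vivo):
    rows = []
    for group, dcts in (("in_vitro", dct_in_vitro), ("in_vivo", dct_in_vivo)):
        for i, dct_value in enumerate(dcts):
            ind = f"{group}-{i}"
            rows.append((ind, group, "placenta_3", "GAPDH", 20.0))
            rows.append((ind, group, "placenta_3", "IGF2", 20.0 + dct_value))
    return pd.DataFrame(
        rows, columns=["individual_id", "group", "tissue", "gene", "ct"]
    )


class TestDdct:
    def test_identical_groups_give_unit_fold(self):
        table = _ct_table([5.0, 5.1, 4.9], [5.0, 5.1, 4.9])
        res = ddct(table, "IGF2")
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value > 0.9

    def test_one_cycle_shift_halves_expression(self):
        table = _ct_table([6.0, 6.0], [5.0, 5.0])
        res = ddct(table, "IGF2")
        assert res.fold_change == pytest.approx(0.5)

    def test_housekeeping_against_itself_is_exactly_one(self, default_cohort):
        _, cts = default_cohort
        res = ddct(cts, "GAPDH", "GAPDH", tissue="placenta_3")
        assert res.fold_change == 1.0
        assert res.p_value == 1.0

    def test_recovers_injected_fold(self):
        ratios, cts = simulate_cohort(CohortConfig(seed=17))
        res = ddct(cts, "IGF2", tissue="placenta_3")
        assert res.fold_change == pytest.approx(0.52, abs=0.05)
        assert res.gene.value == "IGF2"

    def test_missing_housekeeping_samples_dropped(self, caplog):
        table = _ct_table([5.0, 5.2, 5.1], [5.0, 4.9, 5.1])
        table = table.drop(table[(table["individual_id"] == "in_vitro-0")
                                 & (table["gene"] == "GAPDH")].index)
        with caplog.at_level("WARNING"):
            res = ddct(table, "IGF2")
        assert res.n_in_vitro == 2
        assert "dropping 1 sample" in caplog.text

    def test_group_fully_dropped_is_error(self):
        table = _ct_table([5.0], [5.0, 5.1])
        with pytest.raises(ValueError, match="need >= 2"):
            ddct(table, "IGF2")

    def test_fold_change_table_covers_genes_and_tissues(self, default_cohort):
        _, cts = default_cohort
        table = fold_change_table(cts)
        assert set(table["gene"]) == {"H19", "IGF2", "IGF2R"}
        assert set(table["tissue"]) == {"cord_blood", "placenta_3"}
        assert (table["fold_change"] > 0).all()
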