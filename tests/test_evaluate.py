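import numpy as np
import pytest
from scipy import stats

from sadln.evaluate import (
    EnrichmentReport,
    _batch_logrank_chi2,
    _prep_logrank,
    chi_square_enrichment,
    enrichment_count,
    friedman_compare,
    initial_logrank_batch,
    km_estimate,
    kruskal_wallis,
    logrank_statistic,
    permutation_pvalue_enrichment,
    permutation_pvalue_logrank,
)


def hand_logrank_chi2(time, event, group):
    """Independent observed-minus-expected tabulation over event times."""
    time, event, group = map(np.asarray, (time, event, group))
    u = e_a = v = 0.0
    o_a = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & (group == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n - d) / (n - 1) * (n_a / n) * (1 - n_a / n)
    return (o_a - e_a) ** 2 / v


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        lab = np.array([0, 0, 0, 1, 1, 1])
        chi2, df, p = logrank_statistic(t, e, lab)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_tabulation_two_groups(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        lab = np.array([0, 0, 1, 1])
        chi2, df, _ = logrank_statistic(t, e, lab)
        assert chi2 == pytest.approx(hand_logrank_chi2(t, e, lab), abs=1e-10)
        assert chi2 == pytest.approx(49.0 / 17.0, abs=1e-10)

    def test_label_name_invariance(self, rng):
        t = rng.exponential(5, 60)
        e = (rng.random(60) < 0.7).astype(int)
        lab = rng.integers(0, 2, 60)
        chi2a, _, _ = logrank_statistic(t, e, lab)
        chi2b, _, _ = logrank_statistic(t, e, np.where(lab == 0, "x", "y"))
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            logrank_statistic([1.0, 2.0], [0, 0], [0, 1])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_lifelines(self, k):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(k)
        t = rng.exponential(10, 150)
        e = (rng.random(150) < 0.8).astype(int)
        lab = rng.integers(0, k, 150)
        chi2, df, p = logrank_statistic(t, e, lab)
        ref = multivariate_logrank_test(t, lab, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    @pytest.mark.parametrize("k", [2, 4])
    def test_batch_path_matches_loop_path(self, k):
        rng = np.random.default_rng(10 + k)
        t = np.round(rng.exponential(10, 80), 1)  # ties on purpose
        e = (rng.random(80) < 0.7).astype(int)
        prep = _prep_logrank(t, e, k)
        labs = rng.integers(0, k, size=(25, 80))
        # every group must be represented in each row
        labs[:, :k] = np.arange(k)
        batch = _batch_logrank_chi2(prep, labs)
        for row, expected in zip(labs, batch):
            chi2, _, _ = logrank_statistic(t, e, row)
            assert expected == pytest.approx(chi2, abs=1e-8)


class TestPermutationLogrank:
    def test_initial_batch_formula(self):
        assert initial_logrank_batch(0.5) == 10_000
        assert initial_logrank_batch(1e-6) == 1_000_000
        assert initial_logrank_batch(1e-3) == 10_000
        assert initial_logrank_batch(1e-5) == 1_000_000
        assert initial_logrank_batch(0.0) == 1_000_000

    def test_null_case_stops_after_initial_batch(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        e = np.ones(8, dtype=int)
        lab = np.repeat([0, 1], 4)
        # groups are exact copies: observed statistic 0, every permutation >= it
        res = permutation_pvalue_logrank(t, e, lab, seed=0)
        assert res.p_hat > 0.99
        assert res.n_perm == 10_000
        assert res.stopped_by == "ci_within_10pct"

    def test_estimator_floor_and_ci_ordering(self, rng):
        t = np.concatenate([rng.exponential(2, 50), rng.exponential(40, 50)])
        e = np.ones(100, dtype=int)
        lab = np.repeat([0, 1], 50)
        res = permutation_pvalue_logrank(t, e, lab, seed=1, max_perm=20_000)
        assert 1.0 / (res.n_perm + 1) <= res.p_hat <= 1.0
        assert res.ci_low <= res.p_hat <= res.ci_high

    def test_seeded_rerun_identical(self, rng):
        t = rng.exponential(5, 60)
        e = (rng.random(60) < 0.8).astype(int)
        lab = rng.integers(0, 2, 60)
        r1 = permutation_pvalue_logrank(t, e, lab, seed=42, max_perm=20_000)
        r2 = permutation_pvalue_logrank(t, e, lab, seed=42, max_perm=20_000)
        assert r1.p_hat == r2.p_hat and r1.n_perm == r2.n_perm

    def test_permutation_p_agrees_with_asymptotic(self):
        """For tie-free two-group data the chi-square calibration and the
        permutation calibration must agree within the permutation CI."""
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        e = np.ones(200, dtype=int)
        lab = rng.integers(0, 2, 200)
        _, _, p_asym = logrank_statistic(t, e, lab)
        res = permutation_pvalue_logrank(t, e, lab, seed=5)
        assert res.ci_low <= p_asym <= res.ci_high


class TestKruskalWallis:
    def test_hand_value_tie_free(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-6)

    def test_identical_groups(self):
        h, p = kruskal_wallis([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert h == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        lab = rng.integers(0, 3, 30)
        h1, _ = kruskal_wallis(x, lab)
        h2, _ = kruskal_wallis(np.exp(x), lab)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_missing_values_dropped(self):
        h1, _ = kruskal_wallis([1, 2, 3, 4, np.nan], [0, 0, 1, 1, 1])
        h2, _ = kruskal_wallis([1, 2, 3, 4], [0, 0, 1, 1])
        assert h1 == pytest.approx(h2)


class TestChiSquare:
    def test_independent_table(self):
        cats = ["a"] * 10 + ["b"] * 10 + ["a"] * 10 + ["b"] * 10
        labs = [1] * 20 + [2] * 20
        chi2, p = chi_square_enrichment(cats, labs)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        cats = ["a"] * 20 + ["b"] * 20
        labs = [1] * 20 + [2] * 20
        chi2, p = chi_square_enrichment(cats, labs)
        assert chi2 == pytest.approx(40.0)
        assert p == pytest.approx(stats.chi2.sf(40.0, 1))

    def test_row_swap_invariance(self):
        cats = ["a", "b", "a", "b", "a", "a"]
        l1 = [1, 1, 1, 2, 2, 2]
        l2 = [2, 2, 2, 1, 1, 1]
        assert chi_square_enrichment(cats, l1)[0] == pytest.approx(chi_square_enrichment(cats, l2)[0])

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_enrichment(["a", "a", "a"], [1, 2, 1])


class TestPermutationEnrichment:
    @staticmethod
    def _chi2_stat(data, labels):
        return chi_square_enrichment(data, labels)[0]

    def test_strong_association_stops_after_first_batch(self):
        cats = np.array(["a"] * 20 + ["b"] * 20)
        labs = np.array([1] * 20 + [2] * 20)
        res = permutation_pvalue_enrichment(self._chi2_stat, cats, labs, seed=0)
        assert res.p_hat < 0.01
        assert res.n_perm == 1_000
        assert res.stopped_by == "ci_clear_of_05"

    def test_null_association_large_p(self, rng):
        cats = rng.choice(["a", "b"], 60)
        labs = rng.integers(1, 3, 60)
        res = permutation_pvalue_enrichment(self._chi2_stat, cats, labs, seed=0)
        assert res.p_hat > 0.05
        assert res.stopped_by in ("ci_clear_of_05", "max_iterations")

    def test_seeded_rerun_identical(self, rng):
        cats = rng.choice(["a", "b"], 40)
        labs = rng.integers(1, 3, 40)
        r1 = permutation_pvalue_enrichment(self._chi2_stat, cats, labs, seed=7, max_perm=3_000)
        r2 = permutation_pvalue_enrichment(self._chi2_stat, cats, labs, seed=7, max_perm=3_000)
        assert r1.p_hat == r2.p_hat and r1.n_perm == r2.n_perm


class TestEnrichmentCount:
    def test_cluster_linked_label_detected(self, small_sim):
        _, truth, clinical = small_sim
        report = enrichment_count(clinical, truth, seed=0)
        assert isinstance(report, EnrichmentReport)
        assert report.n_significant >= 1
        assert report.entries["marker"]["test"] == "kruskal_wallis"
        assert report.entries["grade"]["test"] == "chi_square"
        assert report.n_significant <= len(report.entries)

    def test_single_level_label_skipped_with_warning(self):
        import pandas as pd

        from sadln.data import ClinicalTable

        clin = ClinicalTable(
            ["s1", "s2", "s3", "s4"],
            [1.0, 2.0, 3.0, 4.0],
            [1, 1, 1, 1],
            pd.DataFrame({"constant": ["x", "x", "x", "x"], "age": [1.0, 2.0, 3.0, 4.0]}),
        )
        with pytest.warns(UserWarning, match="constant"):
            report = enrichment_count(clin, [1, 1, 2, 2], seed=0)
        assert "constant" not in report.entries
        assert "age" in report.entries


class TestFriedman:
    def test_identical_scores(self):
        chi2, p, _ = friedman_compare(np.ones((4, 3)))
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_ordering_hand_value(self):
        scores = np.array([[3.0, 2.0, 1.0]] * 4) + np.arange(4)[:, None]
        chi2, p, mean_ranks = friedman_compare(scores)
        assert chi2 == pytest.approx(8.0, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(8.0, 2))
        np.testing.assert_allclose(np.sort(mean_ranks), [1.0, 2.0, 3.0])

    def test_method_relabeling_invariance(self, rng):
        scores = rng.normal(size=(6, 4))
        chi2a, pa, _ = friedman_compare(scores)
        perm = rng.permutation(4)
        chi2b, pb, _ = friedman_compare(scores[:, perm])
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        scores = np.round(rng.normal(size=(8, 5)), 1)
        chi2, p, _ = friedman_compare(scores)
        ref = stats.friedmanchisquare(*(scores[:, j] for j in range(5)))
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            friedman_compare(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = km_estimate([5.0, 6.0, 7.0], [0, 0, 0], ["g", "g", "g"])
        _, surv = curves["g"]
        np.testing.assert_allclose(surv, 1.0)

    def test_product_limit_hand_value(self):
        curves = km_estimate([1.0, 2.0, 3.0], [1, 1, 1], ["g", "g", "g"])
        times, surv = curves["g"]
        s_at_2 = surv[times == 2.0][0]
        assert s_at_2 == pytest.approx(1.0 / 3.0)

    def test_curves_non_increasing_start_at_one(self, rng):
        t = rng.exponential(5, 50)
        e = (rng.random(50) < 0.7).astype(int)
        lab = rng.integers(0, 2, 50)
        for times, surv in km_estimate(t, e, lab).values():
            assert surv[0] == 1.0
            assert np.all(np.diff(surv) <= 1e-12)
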