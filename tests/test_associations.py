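"""Association test battery: Cox PH (Breslow), rank tests, correlations,
BH-FDR and Stouffer combination, plus the dispatch layer."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from modnet.associations import (
    adjust_fdr,
    associate_phenotypes,
    breslow_loglik,
    combine_across_cohorts,
    cox_survival_association,
    kruskal_wallis_multiclass,
    pearson_continuous,
    rank_sum_two_class,
    spearman_ordinal,
)
from modnet.types import AssociationResult, PhenotypeTable, ValidationError


class TestCox:
    def test_worked_example_matches_likelihood_scan(self):
        # high-covariate subjects die first: the partial likelihood is
        # monotone, so fit and scan agree at the admissible bound
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1.0, 1.0, 1.0, 1.0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        result = cox_survival_association(x, time, event)
        scan = minimize_scalar(lambda b: -breslow_loglik(b, time, event, x),
                               bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-8})
        assert result.statistic == pytest.approx(scan.x, abs=1e-3)

    def test_nondegenerate_small_example_matches_likelihood_scan(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        result = cox_survival_association(x, time, event)
        scan = minimize_scalar(lambda b: -breslow_loglik(b, time, event, x),
                               bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-8})
        assert abs(scan.x) < 5  # interior maximum
        assert result.statistic == pytest.approx(scan.x, abs=1e-3)

    def test_agrees_with_lifelines_without_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x))
        c = rng.uniform(0, 5, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        ours = cox_survival_association(x, time, event)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"t": time, "e": event, "x": x}),
                duration_col="t", event_col="e")
        # no tied event times -> Efron and Breslow coincide
        assert ours.statistic == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        c = rng.uniform(0, 5, n)
        result = cox_survival_association(x, np.minimum(t, c), (t <= c).astype(float))
        assert abs(result.statistic) < 0.2

    def test_parameter_recovery_log_hr(self):
        estimates = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-0.7 * x))  # hazard exp(0.7 x)
            c = rng.uniform(0, 4.96, n)
            result = cox_survival_association(x, np.minimum(t, c), (t <= c).astype(float))
            estimates.append(result.statistic)
        assert abs(np.median(estimates) - 0.7) <= 0.15

    def test_untestable_cases_flagged_not_raised(self):
        no_events = cox_survival_association([1, 2, 3], [1, 2, 3], [0, 0, 0])
        assert not no_events.testable and "event" in no_events.note
        const = cox_survival_association([1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert not const.testable


def _exact_ranksum_p(x, y):
    """Two-sided p by enumerating all rank splits (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    splits = [sum(c) for c in combinations(ranks, n1)]
    center = n1 * (len(pooled) + 1) / 2
    extreme = sum(abs(s - center) >= abs(obs - center) - 1e-9 for s in splits)
    return extreme / len(splits)


class TestRankSum:
    def test_exact_small_sample(self):
        result = rank_sum_two_class([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert result.p_value == pytest.approx(0.1, abs=1e-12)
        assert result.p_value == pytest.approx(
            _exact_ranksum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])), abs=1e-12)
        assert result.effect_direction == 1

    def test_identical_groups_p_one(self):
        result = rank_sum_two_class([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert result.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_on_random_cases(self, rng):
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, 12.0))
            g1, g2 = x[:5], x[5:]
            result = rank_sum_two_class(np.concatenate([g1, g2]),
                                        ["a"] * 5 + ["b"] * 6)
            assert result.p_value == pytest.approx(_exact_ranksum_p(g1, g2), abs=1e-10)

    def test_large_sample_close_to_permutation_oracle(self, rng):
        n = 50
        score = rng.standard_normal(2 * n)
        labels = np.array(["a"] * n + ["b"] * n)
        result = rank_sum_two_class(score, labels)
        u_obs = stats.mannwhitneyu(score[:n], score[n:]).statistic
        center = n * n / 2
        count = 0
        reps = 10_000
        for _ in range(reps):
            perm = rng.permutation(score)
            u = stats.mannwhitneyu(perm[:n], perm[n:]).statistic
            count += abs(u - center) >= abs(u_obs - center) - 1e-9
        perm_p = count / reps
        assert result.p_value == pytest.approx(perm_p, rel=0.05)

    def test_empty_group_untestable(self):
        result = rank_sum_two_class([1.0, 2.0], ["a", "a"])
        assert not result.testable


class TestKruskalWallis:
    def test_textbook_h_value(self):
        result = kruskal_wallis_multiclass([1, 2, 3, 4, 5, 6], list("aabbcc"))
        assert result.statistic == pytest.approx(32 / 7, abs=1e-10)

    def test_all_equal_degenerates_to_h_zero(self):
        result = kruskal_wallis_multiclass([5.0] * 6, list("aabbcc"))
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_matches_rank_formula_with_ties(self, rng):
        score = np.round(rng.standard_normal(60), 1)  # induce ties
        labels = rng.choice(list("abc"), 60)
        while len(set(labels)) < 3:
            labels = rng.choice(list("abc"), 60)
        result = kruskal_wallis_multiclass(score, labels)
        ranks = stats.rankdata(score)
        n = len(score)
        h = 0.0
        for g in "abc":
            r = ranks[labels == g]
            h += r.sum() ** 2 / len(r)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(score, return_counts=True)
        tie_corr = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        assert result.statistic == pytest.approx(h / tie_corr, abs=1e-10)

    def test_two_groups_redirected(self):
        with pytest.raises(ValidationError, match="rank_sum"):
            kruskal_wallis_multiclass([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestCorrelations:
    def test_pearson_perfect_linear(self):
        assert pearson_continuous([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert pearson_continuous([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_pearson_recovers_population_correlation(self, rng):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        result = pearson_continuous(xy[:, 0], xy[:, 1])
        assert abs(result.statistic - 0.5) <= 0.15

    def test_spearman_rank_difference_formula(self):
        result = spearman_ordinal([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert result.statistic == pytest.approx(0.8, abs=1e-12)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        assert spearman_ordinal(x, np.exp(x)).statistic == pytest.approx(1.0)

    def test_spearman_ties_match_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        result = spearman_ordinal(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = stats.pearsonr(rx, ry).statistic
        assert result.statistic == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_untestable(self):
        assert not pearson_continuous([1, 1, 1], [1, 2, 3]).testable
        assert not spearman_ordinal([1, 2, 3], [2, 2, 2]).testable


def _bh_direct(p):
    """Textbook step-up implementation (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q


class TestFdr:
    def test_worked_example(self):
        q = adjust_fdr([0.005, 0.009, 0.05, 0.5])
        np.testing.assert_allclose(q, [0.018, 0.018, 0.05 * 4 / 3, 0.5], atol=1e-12)

    def test_uniform_vector_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2] * 5), [0.2] * 5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_direct_implementation(self, p):
        np.testing.assert_allclose(adjust_fdr(p), _bh_direct(p), atol=1e-12)

    def test_monotone_in_p_order(self, rng):
        p = rng.uniform(size=40)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    def test_missing_entries_pass_through(self):
        q = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0]) and np.isfinite(q[2])


def _member(p, direction, phenotype="phen"):
    return AssociationResult(module_ref=("c", 1), phenotype=phenotype, test="pearson",
                             statistic=0.0, effect_direction=direction, p_value=p)


class TestStouffer:
    def test_two_equal_positive_members(self):
        p_in = 2 * stats.norm.sf(1.96)
        combined = combine_across_cohorts([_member(p_in, 1), _member(p_in, 1)])
        assert combined.statistic == pytest.approx(2 * 1.96 / math.sqrt(2), abs=1e-6)

    def test_single_member_identity(self):
        combined = combine_across_cohorts([_member(0.04, -1)])
        assert combined.p_value == pytest.approx(0.04, abs=1e-9)
        assert combined.effect_direction == -1

    def test_opposite_members_cancel(self):
        p_in = 2 * stats.norm.sf(1.5)
        combined = combine_across_cohorts([_member(p_in, 1), _member(p_in, -1)])
        assert combined.statistic == pytest.approx(0.0, abs=1e-12)
        assert combined.p_value == pytest.approx(1.0)

    def test_no_testable_members_flagged(self):
        result = combine_across_cohorts([AssociationResult(module_ref=("c", 1),
                                                           phenotype="x", test="cox")])
        assert not result.testable


class TestDispatch:
    def _scores(self, rng, n=40):
        scores = pd.DataFrame(rng.standard_normal((3, n)),
                              index=[1, 2, 3],
                              columns=[f"s{i}" for i in range(n)])
        return scores

    def test_three_modules_two_phenotypes_yield_six_tagged_results(self, rng):
        scores = self._scores(rng)
        phen = PhenotypeTable(
            data=pd.DataFrame({
                "group": ["a", "b"] * 20,
                "level": rng.standard_normal(40),
            }, index=scores.columns),
            schema={"group": "two_class", "level": "continuous"},
        )
        results = associate_phenotypes(scores, phen, cohort="c")
        assert len(results) == 6
        tests = {(r.phenotype, r.test) for r in results}
        assert tests == {("group", "wilcoxon"), ("level", "pearson")}

    def test_planted_effect_has_smallest_fdr(self, rng):
        n = 60
        scores = self._scores(rng, n)
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        sd = scores.loc[1].std(ddof=1)
        scores.loc[1, labels == "b"] += 2 * sd  # 2-sd class shift on module 1
        phen = PhenotypeTable(
            data=pd.DataFrame({"group": labels}, index=scores.columns),
            schema={"group": "two_class"},
        )
        results = {r.module_ref[1]: r for r in associate_phenotypes(scores, phen, cohort="c")}
        assert results[1].fdr < 0.05
        assert results[1].fdr == min(r.fdr for r in results.values())

    def test_missing_phenotype_halves_n_used(self, rng):
        scores = self._scores(rng)
        feature = rng.standard_normal(40)
        feature[20:] = np.nan
        phen = PhenotypeTable(
            data=pd.DataFrame({"level": feature}, index=scores.columns),
            schema={"level": "continuous"},
        )
        results = associate_phenotypes(scores, phen, cohort="c")
        assert all(r.n_used == 20 for r in results)

    def test_survival_columns_pair_into_cox(self, rng):
        scores = self._scores(rng)
        t = rng.exponential(1, 40)
        phen = PhenotypeTable(
            data=pd.DataFrame({"time": t, "event": np.ones(40)}, index=scores.columns),
            schema={"time": "survival_time", "event": "survival_event"},
        )
        results = associate_phenotypes(scores, phen, cohort="c")
        assert {r.test for r in results} == {"cox"}

    def test_tests_invariant_to_sample_order(self, rng):
        n = 30
        score = rng.standard_normal(n)
        feature = rng.standard_normal(n)
        perm = rng.permutation(n)
        r1 = pearson_continuous(score, feature)
        r2 = pearson_continuous(score[perm], feature[perm])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        labels = rng.choice(["a", "b"], n)
        w1 = rank_sum_two_class(score, labels)
        w2 = rank_sum_two_class(score[perm], labels[perm])
        assert w1.p_value == pytest.approx(w2.p_value, abs=1e-12)
        t = rng.exponential(1, n)
        e = np.ones(n)
        c1 = cox_survival_association(score, t, e)
        c2 = cox_survival_association(score[perm], t[perm], e[perm])
        assert c1.statistic == pytest.approx(c2.statistic, abs=1e-8)
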