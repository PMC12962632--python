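"""From-scratch survival statistics against hand calculations and
independent oracles (lifelines, scipy, exact enumeration)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbrisk.survival import (
    SurvivalSample,
    bootstrap_compare,
    concordance_index,
    cox_fit,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    survival_at,
)


def sample(times, events, cov=None):
    return SurvivalSample(np.asarray(times, float), np.asarray(events, int), cov)


class TestKaplanMeier:
    def test_hand_product_limit_three_events(self):
        curve = km_estimate(sample([1, 2, 3], [1, 1, 1]))
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(curve.n_risk) == [3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(sample([5, 8, 13], [0, 0, 0]))
        assert curve.time.size == 0
        assert survival_at(curve, 100.0) == 1.0

    def test_single_subject_event(self):
        curve = km_estimate(sample([5], [1]))
        assert survival_at(curve, 5.0) == 0.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            km_estimate(sample([], []))

    def test_censored_at_event_time_remains_at_risk(self):
        # at t=2 the censored subject still counts in the risk set
        curve = km_estimate(sample([1, 2, 2, 3], [1, 1, 0, 1]))
        assert list(curve.n_risk) == [4, 3, 1]
        assert curve.survival == pytest.approx([3 / 4, 1 / 2, 0.0])

    def test_greenwood_se_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = np.round(rng.exponential(30.0, 200), 1) + 0.1
        e = rng.binomial(1, 0.7, 200)
        curve = km_estimate(sample(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.time)
        theirs = kmf.survival_function_["KM_estimate"].reindex(ours.index)
        assert np.allclose(ours.values, theirs.values)

    def test_km_converges_to_exponential_truth(self, rng):
        lam = 1 / 40.0
        n = 2000
        t = np.maximum(rng.exponential(1 / lam, n), 1e-3)
        c = rng.uniform(36, 120, n)
        curve = km_estimate(sample(np.minimum(t, c), (t <= c).astype(int)))
        for horizon in (12.0, 36.0, 60.0):
            est = survival_at(curve, horizon)
            i = int(np.searchsorted(curve.time, horizon, side="right")) - 1
            se = curve.std_err[i]
            assert abs(est - np.exp(-lam * horizon)) < 3 * se


class TestSurvivalAt:
    def test_before_first_event_is_one(self):
        curve = km_estimate(sample([1, 2, 3], [1, 1, 1]))
        assert survival_at(curve, 0.5) == 1.0

    def test_at_last_event_all_events_is_zero(self):
        curve = km_estimate(sample([1, 2, 3], [1, 1, 1]))
        assert survival_at(curve, 3.0) == 0.0

    def test_step_evaluation_between_events(self):
        curve = km_estimate(sample([1, 2, 3], [1, 1, 1]))
        assert survival_at(curve, 2.5) == pytest.approx(1 / 3)


def _logrank_oracle_2group(t1, e1, t2, e2):
    """Term-by-term O-E accumulation over the pooled event times."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    O1 = E1 = V = 0.0
    for ti in sorted(set(t[e == 1])):
        n = (t >= ti).sum()
        n1 = ((t >= ti) & (g == 0)).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & (g == 0)).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    return (O1 - E1) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = sample([1, 3, 5, 7], [1, 0, 1, 1])
        res = logrank_test([g, g])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_example_matches_term_by_term_oracle(self):
        t1, e1 = np.array([1.0, 4.0, 6.0]), np.array([1, 1, 0])
        t2, e2 = np.array([2.0, 3.0, 5.0]), np.array([1, 0, 1])
        res = logrank_test([sample(t1, e1), sample(t2, e2)])
        assert res.chi2 == pytest.approx(_logrank_oracle_2group(t1, e1, t2, e2))
        assert res.df == 1

    def test_matches_lifelines_on_tied_data(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = np.round(rng.exponential(20.0, 300), 0) + 1.0
        e = rng.binomial(1, 0.8, 300)
        g = rng.integers(0, 3, 300)
        res = logrank_test([sample(t[g == i], e[g == i]) for i in range(3)])
        ll = multivariate_logrank_test(t, g, e)
        assert res.chi2 == pytest.approx(ll.test_statistic)
        assert res.p_value == pytest.approx(ll.p_value)
        assert res.df == 2

    def test_null_rejection_rate_near_nominal_alpha(self):
        rng = np.random.default_rng(777)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            t = np.maximum(rng.exponential(40.0, 200), 1e-3)
            c = rng.uniform(36, 120, 200)
            obs, ev = np.minimum(t, c), (t <= c).astype(int)
            res = logrank_test([sample(obs[:100], ev[:100]), sample(obs[100:], ev[100:])])
            rejections += res.p_value < 0.05
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3 * se

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([sample([1, 2], [1, 1])])


class TestCox:
    def test_mirrored_groups_give_zero_coefficient(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        res = cox_fit(sample(t, e, x))
        assert res.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert res.converged

    def test_recovers_true_log_hazard_ratio(self, rng):
        n = 1000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = np.maximum(rng.exponential(1.0, n) / np.exp(0.7 * x), 1e-3)
        c = rng.uniform(0.5, 3.0, n)
        res = cox_fit(sample(np.minimum(t, c), (t <= c).astype(int), x))
        assert abs(res.beta[0] - 0.7) < 3 * res.std_err[0]
        assert res.hazard_ratio[0] == pytest.approx(np.exp(res.beta[0]))
        assert res.ci_lower[0] < res.hazard_ratio[0] < res.ci_upper[0]

    def test_matches_lifelines_with_efron_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        t = np.ceil(rng.exponential(10.0, n) / np.exp(0.5 * x1 - 0.3 * x2))
        t = np.maximum(t, 1.0)  # integer months: heavy ties
        e = rng.binomial(1, 0.8, n)
        res = cox_fit(sample(t, e, np.column_stack([x1, x2])))
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(res.beta, cph.params_.values, atol=1e-6)
        assert np.allclose(res.std_err, cph.standard_errors_.values, atol=1e-6)

    def test_separation_is_flagged(self):
        t = np.array([1, 2, 3, 10, 11, 12], float)
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0], float)
        res = cox_fit(sample(t, e, x))
        assert res.separation

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(sample([1, 2, 3], [1, 1, 1], np.ones(3)))

    def test_score_test_equals_logrank_on_tie_free_data(self, rng):
        n = 80
        t = rng.exponential(10.0, n) + rng.uniform(0, 1e-4, n)  # tie-free
        e = rng.binomial(1, 0.8, n)
        x = rng.binomial(1, 0.5, n).astype(float)
        res = cox_fit(sample(t, e, x))
        lr = logrank_test([sample(t[x == 0], e[x == 0]), sample(t[x == 1], e[x == 1])])
        assert res.score_chi2 == pytest.approx(lr.chi2, rel=1e-9)


class TestConcordance:
    def test_perfect_ranking_scores_one(self):
        s = sample([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([4, 3, 2, 1], s) == 1.0

    def test_reversed_ranking_scores_zero(self):
        s = sample([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([1, 2, 3, 4], s) == 0.0

    def test_all_tied_scores_give_half(self):
        s = sample([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([7, 7, 7, 7], s) == 0.5

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], sample([1, 2], [0, 0]))

    def test_matches_lifelines_on_censored_data(self, rng):
        from lifelines.utils import concordance_index as ll_cindex

        n = 150
        score = rng.normal(size=n)
        t = rng.exponential(10.0, n) / np.exp(0.8 * score) + rng.uniform(0, 1e-6, n)
        e = rng.binomial(1, 0.7, n)
        ours = concordance_index(score, sample(t, e))
        theirs = ll_cindex(t, -score, e)  # lifelines: higher score = longer survival
        assert ours == pytest.approx(theirs)

    def test_true_risk_score_beats_permuted_score(self, rng):
        n = 300
        score = rng.normal(size=n)
        t = np.maximum(rng.exponential(10.0, n) / np.exp(score), 1e-4)
        e = rng.binomial(1, 0.8, n)
        s = sample(t, e)
        assert concordance_index(score, s) > concordance_index(rng.permutation(score), s)


class TestBootstrapCompare:
    def test_identical_models_center_on_zero(self, rng):
        n = 120
        score = rng.normal(size=n)
        t = np.maximum(rng.exponential(10.0, n), 1e-3)
        e = rng.binomial(1, 0.8, n)
        res = bootstrap_compare(score, score, sample(t, e), n_boot=200, seed=1)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert res.ci_lower <= 0.0 <= res.ci_upper

    def test_informative_score_beats_random_with_ci_excluding_zero(self, rng):
        n = 200
        score = rng.normal(size=n)
        t = np.maximum(rng.exponential(10.0, n) / np.exp(1.2 * score), 1e-4)
        e = np.ones(n, int)
        noise = rng.permutation(score)
        res = bootstrap_compare(score, noise, sample(t, e), n_boot=300, seed=2)
        assert res.ci_lower > 0.0

    def test_too_few_resamples_rejected(self, rng):
        s = sample([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_compare([1, 2, 3], [3, 2, 1], s, n_boot=10)

    def test_reproducible_for_fixed_seed(self, rng):
        n = 80
        a, b = rng.normal(size=n), rng.normal(size=n)
        t = np.maximum(rng.exponential(10.0, n), 1e-3)
        e = rng.binomial(1, 0.7, n)
        s = sample(t, e)
        r1 = bootstrap_compare(a, b, s, n_boot=150, seed=9)
        r2 = bootstrap_compare(a, b, s, n_boot=150, seed=9)
        assert np.array_equal(r1.diffs, r2.diffs)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[2, 2], [2, 2]], 1.0),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(1, 15, size=(2, 2))
            ours = fisher_exact_2x2(table)
            theirs = stats.fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])
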