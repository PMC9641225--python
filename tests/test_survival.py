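"""Product-limit, Mantel-Cox and Efron-Cox estimators against hand
computations and an independent library."""

import math

import numpy as np
import pytest

from mmrd_burden.survival import (
    SurvivalOutcome,
    cox_fit,
    km_estimate,
    logrank_test,
    pairwise_logrank,
    spearman_screen,
)
from mmrd_burden.survival import _efron_loglik_grad_hess


def outcomes(times, events):
    return [SurvivalOutcome(t, e) for t, e in zip(times, events)]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate(outcomes([1, 2, 3], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.survival_at(0.5) == 1.0
        assert km.survival_at(1.5) == pytest.approx(2 / 3)

    def test_hand_product_limit_with_censoring(self):
        # censored subject at t=2 leaves the risk set; at t=3 one of one dies
        km = km_estimate(outcomes([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == 0.0

    def test_all_censored_survival_stays_one(self):
        km = km_estimate(outcomes([1, 2, 3], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_censored_at_event_time_still_at_risk(self):
        # subject censored exactly at t=2 counts in the t=2 risk set
        km = km_estimate(outcomes([2, 2, 5], [1, 0, 1]))
        assert km.survival_at(2) == pytest.approx(2 / 3)

    def test_greenwood_log_ci_hand_computation(self):
        km = km_estimate(outcomes([1, 2, 3, 4, 5], [1, 1, 0, 1, 0]))
        # at t=2: S=0.6, Greenwood sum = 1/(5*4) + 1/(4*3)
        g = 1 / 20 + 1 / 12
        z = 1.959963984540054
        i = list(km.event_times).index(2.0)
        assert km.survival[i] == pytest.approx(0.6)
        assert km.ci_lower[i] == pytest.approx(0.6 * math.exp(-z * math.sqrt(g)), rel=1e-9)
        assert km.ci_upper[i] == pytest.approx(
            min(1.0, 0.6 * math.exp(z * math.sqrt(g))), rel=1e-9
        )

    def test_curve_monotone_and_bands_ordered(self):
        rng = np.random.default_rng(3)
        km = km_estimate(
            outcomes(rng.exponential(10, 50), rng.integers(0, 2, 50))
        )
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.ci_lower <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_upper + 1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        t = rng.exponential(12, 80)
        e = (rng.random(80) > 0.35).astype(int)
        km = km_estimate(outcomes(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for ti in km.event_times:
            assert km.survival_at(ti) == pytest.approx(float(kmf.predict(ti)), abs=1e-10)


def _two_group_logrank_hand(t1, e1, t2, e2):
    """Direct two-group Mantel-Cox sums, written independently of the
    k-group matrix implementation."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e, var = 0.0, 0.0
    for ti in np.unique(t[e == 1]):
        n = (t >= ti).sum()
        n1 = ((t >= ti) & (g == 0)).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        g = outcomes([1, 2, 3, 4], [1, 1, 0, 1])
        r = logrank_test([g, g])
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_match_hand_computation(self):
        t1, e1 = np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])
        t2, e2 = np.array([10.0, 11.0, 12.0]), np.array([1, 1, 1])
        r = logrank_test([outcomes(t1, e1), outcomes(t2, e2)])
        assert r.chi_square == pytest.approx(_two_group_logrank_hand(t1, e1, t2, e2))
        assert r.dof == 1

    def test_matches_lifelines_with_ties_and_censoring(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(5)
        t1 = np.round(rng.exponential(8, 40), 0) + 1
        t2 = np.round(rng.exponential(14, 35), 0) + 1
        e1 = (rng.random(40) > 0.3).astype(int)
        e2 = (rng.random(35) > 0.3).astype(int)
        r = logrank_test([outcomes(t1, e1), outcomes(t2, e2)])
        ref = ll(t1, t2, e1, e2)
        assert r.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert r.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        gs = [
            outcomes(rng.exponential(10, 20), rng.integers(0, 2, 20)) for _ in range(3)
        ]
        a = logrank_test(gs)
        b = logrank_test(gs[::-1])
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-9)
        assert a.dof == 2

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([outcomes([1, 2], [0, 0]), outcomes([3], [0])])

    def test_permutation_null_p_values_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(42)
        t = rng.exponential(10, 30)
        e = (rng.random(30) > 0.25).astype(int)
        pvals = []
        for _ in range(1000):
            lab = rng.permutation(30) < 15
            pvals.append(
                logrank_test([outcomes(t[lab], e[lab]), outcomes(t[~lab], e[~lab])]).p_value
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPairwise:
    def test_three_identical_groups_all_p_one(self):
        g = outcomes([1, 2, 3, 5, 8], [1, 0, 1, 1, 0])
        res = pairwise_logrank({"a": g, "b": g, "c": g})
        assert all(r.p_value == pytest.approx(1.0) for r in res.values())

    def test_two_categories_equals_single_test(self):
        rng = np.random.default_rng(2)
        ga = outcomes(rng.exponential(5, 25), rng.integers(0, 2, 25))
        gb = outcomes(rng.exponential(15, 25), rng.integers(0, 2, 25))
        pw = pairwise_logrank({"a": ga, "b": gb})
        direct = logrank_test([ga, gb])
        assert pw[("a", "b")].chi_square == pytest.approx(direct.chi_square)
        assert pw[("a", "b")] == pw[("b", "a")]

    def test_bonferroni_scales_p(self):
        rng = np.random.default_rng(4)
        gs = {
            k: outcomes(rng.exponential(m, 20), np.ones(20, dtype=int))
            for k, m in [("a", 3), ("b", 9), ("c", 27)]
        }
        raw = pairwise_logrank(gs)
        adj = pairwise_logrank(gs, bonferroni=True)
        for key in raw:
            assert adj[key].p_value == pytest.approx(min(1.0, raw[key].p_value * 3))


class TestCox:
    def test_matches_lifelines_with_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = np.ceil(rng.exponential(10 * np.exp(-0.8 * x + 0.3 * z)))
        e = (rng.random(n) > 0.3).astype(int)
        fit = cox_fit({"x": x, "z": z}, outcomes(t, e))
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x, "z": z}), "t", "e"
        )
        assert fit.converged
        assert fit.coef == pytest.approx(ref.params_.values, abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_.values, abs=1e-5)

    def test_score_test_at_zero_equals_logrank(self):
        # tie-free fixture: the Cox score statistic at beta=0 for a binary
        # covariate is exactly the log-rank chi-square
        rng = np.random.default_rng(14)
        n = 40
        x = (np.arange(n) < 20).astype(float)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        e = (rng.random(n) > 0.3).astype(int)
        assert len(np.unique(t)) == n
        _, grad, hess = _efron_loglik_grad_hess(np.zeros(1), x[:, None], t, e)
        score_chi2 = float(grad[0] ** 2 / -hess[0, 0])
        lr = logrank_test([outcomes(t[x == 1], e[x == 1]), outcomes(t[x == 0], e[x == 0])])
        assert score_chi2 == pytest.approx(lr.chi_square, abs=1e-6)

    def test_hr_ci_and_p_consistent(self):
        rng = np.random.default_rng(21)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 * np.exp(-1.0 * x))
        e = np.ones(n, dtype=int)
        fit = cox_fit({"x": x}, outcomes(t, e))
        assert fit.hazard_ratio[0] == pytest.approx(math.exp(fit.coef[0]))
        assert fit.ci_lower[0] < fit.hazard_ratio[0] < fit.ci_upper[0]
        assert 0.0 <= fit.p_value[0] <= 1.0

    def test_constant_covariate_rejected(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 0]
        with pytest.raises(ValueError, match="constant"):
            cox_fit({"x": [1.0, 1.0, 1.0, 1.0]}, outcomes(t, e))

    def test_more_covariates_than_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(
                {"a": [0.0, 1.0, 0.5], "b": [1.0, 0.0, 0.5]},
                outcomes([1, 2, 3], [1, 0, 0]),
            )

    def test_null_coverage_binary_covariate(self):
        # true HR 1: the 95% Wald CI should contain 0 (log scale) in at
        # least 93% of simulated cohorts of the study's size and censoring
        rng = np.random.default_rng(1234)
        n, reps, covered = 61, 500, 0
        for _ in range(reps):
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(10.0, n)
            c = rng.exponential(12.0, n)  # ~45% censoring
            obs = np.minimum(t, c)
            e = (t <= c).astype(int)
            fit = cox_fit({"x": x}, outcomes(obs, e))
            if fit.ci_lower[0] <= 1.0 <= fit.ci_upper[0]:
                covered += 1
        assert covered / reps >= 0.93


class TestSpearmanScreen:
    def test_monotone_and_antimonotone(self):
        x = np.linspace(-3, 3, 25)
        screen = spearman_screen({"x": x, "cube": x**3, "neg": -x})
        names = screen.names
        m = screen.matrix
        assert m[names.index("x"), names.index("cube")] == pytest.approx(1.0)
        assert m[names.index("x"), names.index("neg")] == pytest.approx(-1.0)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_independent_samples_below_threshold(self):
        rng = np.random.default_rng(6)
        screen = spearman_screen(
            {"a": rng.uniform(size=1000), "b": rng.uniform(size=1000)}
        )
        assert abs(screen.matrix[0, 1]) < 0.1
        assert screen.flagged_pairs == []

    def test_flagging_at_threshold(self):
        x = np.linspace(0, 1, 30)
        screen = spearman_screen({"x": x, "y": x**2, "z": -x}, threshold=0.8)
        flagged = {(a, b) for a, b, _ in screen.flagged_pairs}
        assert ("x", "y") in flagged and ("x", "z") in flagged

    def test_too_few_complete_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_screen({"a": [1.0, 2.0, np.nan], "b": [1.0, np.nan, 3.0]})
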