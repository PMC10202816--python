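"""Kaplan-Meier, log-rank, Cox and concordance against hand/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from micoprog.survival import (
    density_matched_subsampling,
    fit_coxph,
    harrell_c,
    km_estimate,
    logrank_test,
)


def records(times, events, index=None):
    return pd.DataFrame(
        {"time": times, "event": events},
        index=index or [f"p{i}" for i in range(len(times))],
    )


class TestKaplanMeier:
    def test_single_event(self):
        curve = km_estimate(records([5.0], [1]))
        assert curve.survival_at(4.999) == 1.0
        assert curve.survival_at(5.0) == 0.0
        assert curve.survival_at(6.0) == 0.0

    def test_all_censored(self):
        curve = km_estimate(records([1, 2, 3.0], [0, 0, 0]))
        assert curve.survival_at(10.0) == 1.0

    def test_hand_product_limit(self):
        # censored at 1; events at 2, 3, 4. Risk sets: {2,3,4} at t=2 so
        # S = 2/3; {3,4} at t=3 so S = 2/3 * 1/2 = 1/3; {4} at t=4 so S = 0
        curve = km_estimate(records([1, 2, 3, 4.0], [0, 1, 1, 1]))
        assert curve.survival_at(1.5) == pytest.approx(1.0)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3.5) == pytest.approx(1 / 3)
        assert curve.survival_at(4.5) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical(self, rng):
        times = rng.exponential(1.0, 25).round(3) + 0.001
        curve = km_estimate(records(times, [1] * 25))
        for t in (0.2, 0.5, 1.0, 2.0):
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(records([0.0, 1.0], [1, 1]))


def brute_force_logrank(times, events, groups):
    """Textbook observed-minus-expected tabulation over event times (2 groups)."""
    times, events, groups = map(np.asarray, (times, events, groups))
    labels = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        rec = records([1, 2, 3, 1, 2, 3.0], [1, 1, 0, 1, 1, 0])
        chi2, p = logrank_test(rec, ["a", "a", "a", "b", "b", "b"])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_tabulation(self):
        times = [1, 2, 3, 4, 5, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        chi2, _ = logrank_test(records(times, events), groups)
        assert chi2 == pytest.approx(brute_force_logrank(times, events, groups), abs=1e-9)

    def test_invariant_to_monotone_time_rescaling(self, rng):
        times = rng.exponential(1.0, 30) + 0.01
        events = rng.integers(0, 2, 30)
        events[0] = 1
        groups = rng.choice(["a", "b"], 30)
        chi2_a, _ = logrank_test(records(times, events), list(groups))
        chi2_b, _ = logrank_test(records(np.exp(times), events), list(groups))
        assert chi2_a == pytest.approx(chi2_b, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(records([1, 2.0], [1, 1]), ["a", "a"])


def brute_force_cox_1cov(times, events, x, grid=None):
    """Grid-search maximization of the (no-ties) Cox partial likelihood."""
    times, events, x = map(np.asarray, (times, events, x))
    grid = grid if grid is not None else np.arange(-5, 5, 1e-4)
    best, best_ll = None, -np.inf
    for beta in grid:
        ll = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        if ll > best_ll:
            best, best_ll = beta, ll
    return best


class TestCox:
    def test_matches_partial_likelihood_grid_search(self):
        times = [1.0, 2.0, 3.5, 4.0, 5.5, 6.0, 7.5, 9.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        x = [1, 0, 1, 0, 1, 0, 0, 1]
        fit = fit_coxph(records(times, events), pd.Series(x, index=[f"p{i}" for i in range(8)], name="x"),
                        enforce_min_group=False)
        oracle = brute_force_cox_1cov(times, events, x)
        assert fit.summary.loc["x", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_min_group_guard(self):
        n = 19
        times = np.arange(1, n + 1, dtype=float)
        events = [1] * n
        x = [1] * 9 + [0] * 10
        rec = records(times, events)
        cov = pd.Series(x, index=rec.index, name="g")
        with pytest.raises(ValueError, match="minimum"):
            fit_coxph(rec, cov)
        fit = fit_coxph(rec, cov, enforce_min_group=False)
        assert np.isfinite(fit.summary.loc["g", "coef"])

    def test_coefficient_recovery_within_3se(self, rng):
        hits = 0
        for rep in range(30):
            local = np.random.default_rng(rep)
            n = 150
            x = local.normal(size=n)
            t = local.exponential(1.0, n) / np.exp(0.7 * x)
            c = local.uniform(0, 3, n)
            obs = np.minimum(t, c)
            ev = (t <= c).astype(int)
            fit = fit_coxph(records(obs + 1e-9, ev), pd.Series(x, index=[f"p{i}" for i in range(n)], name="x"))
            coef = fit.summary.loc["x", "coef"]
            se = (np.log(fit.summary.loc["x", "ci_upper"]) - coef) / 1.959963984540054
            hits += abs(coef - 0.7) <= 3 * se
        assert hits >= 29

    def test_breslow_close_to_efron_without_ties(self, rng):
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.5 * x)
        rec = records(t + 1e-9, [1] * n)
        cov = pd.Series(x, index=rec.index, name="x")
        efron = fit_coxph(rec, cov).summary.loc["x", "coef"]
        breslow = fit_coxph(rec, cov, ties_method="breslow").summary.loc["x", "coef"]
        assert efron == pytest.approx(breslow, abs=1e-4)


def brute_force_c(scores, times, events):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            usable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_and_tied(self):
        times = [1.0, 2.0, 3.0, 4.0]
        rec = records(times, [1, 1, 1, 1])
        assert harrell_c(np.array([-1.0, -2.0, -3.0, -4.0]), rec) == 1.0
        assert harrell_c(np.array([0.0, 0.0, 0.0, 0.0]), rec) == 0.5

    def test_matches_brute_force(self, rng):
        n = 20
        times = rng.exponential(1.0, n) + 0.01
        events = rng.integers(0, 2, n)
        events[:2] = 1
        scores = rng.normal(size=n)
        scores[5] = scores[6]  # plant a score tie
        rec = records(times, events)
        assert harrell_c(scores, rec) == pytest.approx(
            brute_force_c(scores, times, events), abs=1e-12
        )

    def test_antisymmetry_without_ties(self, rng):
        n = 25
        times = np.sort(rng.exponential(1.0, n)) + 0.01
        events = rng.integers(0, 2, n)
        events[0] = 1
        scores = rng.normal(size=n)
        rec = records(times, events)
        assert harrell_c(-scores, rec) == pytest.approx(1 - harrell_c(scores, rec), abs=1e-12)


class TestSubsampling:
    @staticmethod
    def _cohort(seed, n=160):
        local = np.random.default_rng(seed)
        score = local.normal(0, 1, n)
        x = local.normal(0, 1, n)
        t = local.exponential(1.0, n)
        rec = records(t + 1e-6, [1] * n)
        return rec, score, x

    def test_deterministic_memberships(self):
        rec, score, x = self._cohort(0)
        kwargs = dict(n_subsets=4, subset_size=50, seed=9)
        a = density_matched_subsampling(rec, score, np.random.default_rng(1).normal(0, 1, 200), x, **kwargs)
        b = density_matched_subsampling(rec, score, np.random.default_rng(1).normal(0, 1, 200), x, **kwargs)
        for m1, m2 in zip(a.subsets_matched, b.subsets_matched):
            np.testing.assert_array_equal(m1, m2)
        assert (a.significant_uniform, a.significant_matched) == (
            b.significant_uniform,
            b.significant_matched,
        )

    def test_degenerate_target_density_rejected(self):
        rec, score, x = self._cohort(1)
        with pytest.raises(ValueError, match="degenerate"):
            density_matched_subsampling(rec, np.zeros(len(rec)), np.zeros(50), x, n_subsets=2, subset_size=40)
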