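import numpy as np
import pandas as pd
import pytest

from ftirsurv.survival import (
    backward_wald,
    cox_fit,
    km_estimate,
    logrank_test,
    survival_at,
)
from ftirsurv.survival import _partial_loglik


def simulate_cox_data(n, beta, rng, censor_frac=0.2):
    """Exponential survival with a single binary covariate."""
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = np.where(rng.random(n) < censor_frac, rng.uniform(0, t.max(), n), np.inf)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return pd.DataFrame({"x": x}), times, events


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert survival_at(curve, 100) == 1.0

    def test_hand_product_limit(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert survival_at(curve, 1) == pytest.approx(2 / 3)
        assert survival_at(curve, 2.5) == pytest.approx(2 / 3)
        assert survival_at(curve, 3) == pytest.approx(0.0)

    def test_right_continuous_horizon_evaluation(self):
        curve = km_estimate([36, 40], [1, 0])
        # the step at t=36 is already taken when evaluating at 36
        assert survival_at(curve, 36) == pytest.approx(0.5)
        assert survival_at(curve, 35.99) == pytest.approx(1.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(31)
        times = rng.exponential(10, size=50).round(1)
        curve = km_estimate(times, np.ones_like(times))
        for t in np.unique(times):
            ecdf = np.mean(times <= t)
            assert survival_at(curve, t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4], [1, 0, 1, 0]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_life_table(self):
        # A events {1, 2}; B events {3, 4}; no censoring.
        # O_A - E_A = 2 - (1/2 + 1/3) = 7/6; V = 1/4 + 2/9 = 17/36
        # chi2 = (7/6)^2 / (17/36) = 49/17
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-10)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(49 / 17, 1), abs=1e-10)

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(32)
        ta, tb = rng.exponential(5, 20), rng.exponential(9, 15)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 15)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_censoring_time_beyond_last_event_is_irrelevant(self):
        # moving a censoring time around past the last event changes nothing
        chi2_a, _ = logrank_test([1, 2, 5], [1, 1, 0], [3, 4], [1, 1])
        chi2_b, _ = logrank_test([1, 2, 99], [1, 1, 0], [3, 4], [1, 1])
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1, 2], [0, 0], [3], [0])


class TestCoxFit:
    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(33)
        X, times, events = simulate_cox_data(500, np.log(3.0), rng)
        model = cox_fit(X, times, events)
        assert model.ci_lower[0] < 3.0 < model.ci_upper[0]
        assert model.hr[0] == pytest.approx(3.0, rel=0.25)

    def test_efron_breslow_agree_without_ties(self):
        rng = np.random.default_rng(34)
        X, times, events = simulate_cox_data(120, 0.8, rng)
        assert np.unique(times[events == 1]).size == events.sum()  # no ties
        b_e = cox_fit(X, times, events, ties="efron").beta
        b_b = cox_fit(X, times, events, ties="breslow").beta
        assert np.allclose(b_e, b_b, atol=1e-8)

    def test_score_vanishes_at_optimum(self):
        rng = np.random.default_rng(35)
        X, times, events = simulate_cox_data(200, 0.5, rng)
        X["z"] = rng.normal(size=200)
        model = cox_fit(X, times, events)
        _, score, _ = _partial_loglik(
            model.beta, X.to_numpy(float), np.asarray(times), np.asarray(events), "efron"
        )
        assert np.abs(score).max() < 1e-6

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(36)
        X, times, events = simulate_cox_data(150, 1.0, rng)
        model = cox_fit(X, times, events, ties="efron")
        df = X.copy()
        df["T"], df["E"] = times, events
        ll = CoxPHFitter().fit(df, "T", "E")
        assert model.beta[0] == pytest.approx(ll.params_["x"], abs=1e-5)
        assert model.se[0] == pytest.approx(ll.standard_errors_["x"], abs=1e-5)

    def test_beta_sign_matches_logrank_direction(self):
        rng = np.random.default_rng(37)
        X, times, events = simulate_cox_data(80, 1.2, rng, censor_frac=0.0)
        model = cox_fit(X, times, events)
        grp = X["x"].to_numpy() == 1
        # positive beta: the x=1 group has more events than expected
        t1, e1 = times[grp], events[grp]
        t0, e0 = times[~grp], events[~grp]
        from lifelines.statistics import logrank_test as ll_lr

        res = ll_lr(t1, t0, event_observed_A=e1, event_observed_B=e0)
        assert model.beta[0] > 0
        assert res.p_value < 0.05

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="'x'"):
            cox_fit(X, [1, 2, 3, 4], [1, 1, 0, 1])

    def test_separation_flagged(self):
        # covariate perfectly orders the event times: monotone likelihood
        X = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 10})
        times = list(range(1, 11)) + list(range(50, 60))
        events = [1] * 20
        model = cox_fit(X, times, events)
        assert "x" in model.separation

    def test_hazard_ratio_invariants(self):
        rng = np.random.default_rng(38)
        X, times, events = simulate_cox_data(100, 0.5, rng)
        m = cox_fit(X, times, events)
        assert (m.hr > 0).all()
        assert (m.ci_lower <= m.hr).all() and (m.hr <= m.ci_upper).all()
        assert ((m.wald_p > 0) & (m.wald_p <= 1)).all()


class TestBackwardWald:
    def test_no_removal_when_all_significant(self):
        rng = np.random.default_rng(39)
        x1 = rng.integers(0, 2, 400).astype(float)
        x2 = rng.integers(0, 2, 400).astype(float)
        times = rng.exponential(1.0 / (0.1 * np.exp(1.5 * x1 + 1.0 * x2)))
        events = np.ones(400, dtype=int)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        model = backward_wald(X, times, events, alpha_remove=0.10)
        assert model.elimination_trace == ()
        assert set(model.covariates) == {"x1", "x2"}

    def test_null_covariate_is_first_elimination_candidate(self):
        """A planted-null covariate among informative ones tops the removal order."""
        rng = np.random.default_rng(40)
        null_first = 0
        n_rep = 200
        for _ in range(n_rep):
            X, times, events = simulate_cox_data(100, 1.0, rng)
            X["noise"] = rng.normal(size=100)
            model = backward_wald(X, times, events, alpha_remove=0.10)
            full = model.initial_model
            first_candidate = full.covariates[int(np.argmax(full.wald_p))]
            if first_candidate == "noise":
                null_first += 1
            if model.elimination_trace:
                # anything actually removed must start with the top candidate
                assert model.elimination_trace[0][0] == first_candidate
        assert null_first >= 0.9 * n_rep

    def test_trace_and_initial_model_recorded(self):
        rng = np.random.default_rng(41)
        X, times, events = simulate_cox_data(150, 1.0, rng)
        X["noise"] = rng.normal(size=150)
        model = backward_wald(X, times, events)
        assert model.initial_model is not None
        assert set(model.initial_model.covariates) == {"x", "noise"}
        for name, p in model.elimination_trace:
            assert p > 0.10
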