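"""Closed-form survival functions, censored MLE, and AIC/BIC selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from btc_cea.survival import (
    Family,
    FitResult,
    ParametricModelSpec,
    fit_all,
    fit_mle,
    select_best,
    survival_at,
)


def loglogistic_sf(t, shape, scale):
    # independent hand formula (no scipy): S(t) = 1 / (1 + (t/scale)^shape)
    return 1.0 / (1.0 + (t / scale) ** shape)


class TestClosedForms:
    def test_loglogistic_anchor_points(self):
        spec = ParametricModelSpec(Family.LOGLOGISTIC, (1.81, 13.55))
        assert survival_at(spec, 0.0) == 1.0
        # median of the log-logistic equals its scale parameter
        assert survival_at(spec, 13.55) == pytest.approx(0.5, abs=1e-12)
        expected = loglogistic_sf(24.0, 1.81, 13.55)  # = 0.26216...
        assert expected == pytest.approx(0.2622, abs=5e-4)
        assert survival_at(spec, 24.0) == pytest.approx(expected, rel=1e-10)

    def test_gamma_survival_vs_numerical_integration(self):
        shape, rate = 2.76, 0.38
        spec = ParametricModelSpec(Family.GAMMA, (shape, rate))

        def density(x):
            return rate**shape * x ** (shape - 1) * math.exp(-rate * x) / math.gamma(shape)

        expected, _ = integrate.quad(density, 6.0, np.inf)
        assert expected == pytest.approx(0.5409, abs=1e-3)
        assert survival_at(spec, 6.0) == pytest.approx(expected, rel=1e-8)

    def test_negative_time_rejected(self):
        spec = ParametricModelSpec(Family.WEIBULL, (1.2, 5.0))
        with pytest.raises(ValueError):
            spec.survival(-1.0)

    @pytest.mark.parametrize("family,params", [
        (Family.WEIBULL, (0.0, 1.0)),
        (Family.GAMMA, (1.0, -2.0)),
        (Family.LOGLOGISTIC, (-1.0, 5.0)),
        (Family.GOMPERTZ, (-0.1, 0.2)),  # improper survival distribution
        (Family.EXPONENTIAL, (0.0,)),
    ])
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValueError):
            ParametricModelSpec(family, params)


_param_strategies = {
    Family.EXPONENTIAL: st.tuples(st.floats(0.01, 2.0)),
    Family.WEIBULL: st.tuples(st.floats(0.3, 4.0), st.floats(0.5, 40.0)),
    Family.GAMMA: st.tuples(st.floats(0.3, 6.0), st.floats(0.02, 2.0)),
    Family.LOGNORMAL: st.tuples(st.floats(-1.0, 3.5), st.floats(0.2, 2.0)),
    Family.LOGLOGISTIC: st.tuples(st.floats(0.5, 4.0), st.floats(0.5, 40.0)),
    Family.GOMPERTZ: st.tuples(st.floats(0.01, 1.0), st.floats(0.01, 1.0)),
}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data(), family=st.sampled_from(list(Family)))
def test_survival_function_properties(data, family):
    """Any valid spec: S(0)=1, S in [0,1], non-increasing, hazard >= 0."""
    params = data.draw(_param_strategies[family])
    spec = ParametricModelSpec(family, params)
    t = np.linspace(0.0, 120.0, 241)
    s = spec.survival(t)
    assert s[0] == pytest.approx(1.0)
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-12)
    alive = s > 1e-300
    assert np.all(spec.hazard(t)[alive] >= 0.0)


class TestFitting:
    def test_exponential_mle_matches_closed_form_exactly(self):
        fit = fit_mle([1.0, 2.0, 3.0], [1, 1, 1], Family.EXPONENTIAL)
        assert fit.spec.params[0] == pytest.approx(3.0 / 6.0, abs=0)
        assert fit.converged

    def test_exponential_recovery_from_simulation(self, rng):
        t = rng.exponential(scale=10.0, size=1000)  # rate 0.1
        fit = fit_mle(t, np.ones_like(t), Family.EXPONENTIAL)
        closed_form = 1000 / t.sum()
        assert fit.spec.params[0] == pytest.approx(closed_form, rel=1e-12)
        assert fit.spec.params[0] == pytest.approx(0.1, rel=0.10)

    def test_all_censored_raises_no_events(self):
        with pytest.raises(ValueError, match="no events"):
            fit_mle([1.0, 2.0], [0, 0], Family.WEIBULL)

    def test_loglogistic_recovery_with_censoring(self, rng):
        truth = ParametricModelSpec(Family.LOGLOGISTIC, (1.81, 13.55))
        n = 5000
        t_true = truth.rvs(n, rng)
        cens = rng.uniform(0.0, np.quantile(t_true, 0.95) * 1.6, n)
        obs = np.minimum(t_true, cens)
        ev = (t_true <= cens).astype(int)
        assert 0.1 < 1 - ev.mean() < 0.5  # meaningful censoring fraction
        fit = fit_mle(obs, ev, Family.LOGLOGISTIC)
        for got, want in zip(fit.spec.params, truth.params):
            assert got == pytest.approx(want, rel=0.10)

    def test_gamma_recovery_with_censoring(self, rng):
        truth = ParametricModelSpec(Family.GAMMA, (2.76, 0.38))
        n = 5000
        t_true = truth.rvs(n, rng)
        cens = rng.uniform(0.0, np.quantile(t_true, 0.95) * 1.6, n)
        obs = np.minimum(t_true, cens)
        ev = (t_true <= cens).astype(int)
        fit = fit_mle(obs, ev, Family.GAMMA)
        for got, want in zip(fit.spec.params, truth.params):
            assert got == pytest.approx(want, rel=0.15)

    @pytest.mark.parametrize("family", [f for f in Family if f != Family.EXPONENTIAL])
    def test_fitted_loglik_never_below_truth(self, family, rng):
        """On the fitting sample the MLE cannot score worse than the generator."""
        params = {
            Family.WEIBULL: (1.4, 10.0), Family.GAMMA: (2.76, 0.38),
            Family.LOGNORMAL: (2.0, 0.7), Family.LOGLOGISTIC: (2.19, 7.07),
            Family.GOMPERTZ: (0.08, 0.05),
        }[family]
        truth = ParametricModelSpec(family, params)
        t = truth.rvs(400, rng)
        ev = np.ones_like(t)
        fit = fit_mle(t, ev, family)
        assert fit.loglik >= truth.loglik(t, ev) - 1e-6


class TestSelection:
    def test_aic_bic_formulas(self):
        # hand-computed for loglik=-100, k=2, n=50
        spec = ParametricModelSpec(Family.WEIBULL, (1.0, 1.0))
        fit = FitResult(spec, loglik=-100.0, n=50, converged=True)
        assert fit.aic == pytest.approx(2 * 2 - 2 * (-100.0))           # 204
        assert fit.bic == pytest.approx(2 * math.log(50) + 200.0)       # 207.82...

    def test_min_aic_wins_and_bic_breaks_ties(self):
        s1 = ParametricModelSpec(Family.WEIBULL, (1.0, 1.0))
        s2 = ParametricModelSpec(Family.GAMMA, (1.0, 1.0))
        a = FitResult(s1, loglik=-100.0, n=50, converged=True)   # aic 204
        b = FitResult(s2, loglik=-103.0, n=50, converged=True)   # aic 210
        assert select_best([a, b]) is a
        # equal AIC: lower BIC wins (same k, larger n => larger bic)
        c = FitResult(s1, loglik=-100.0, n=50, converged=True)
        d = FitResult(s2, loglik=-100.0, n=200, converged=True)
        assert select_best([d, c]) is c

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_loglogistic_selected_across_replicates(self):
        """AIC/BIC picks the generating family in >= 80% of replicates."""
        rng = np.random.default_rng(1234)
        truth = ParametricModelSpec(Family.LOGLOGISTIC, (2.19, 7.07))
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            t = truth.rvs(2000, rng)
            best = select_best(fit_all(t, np.ones_like(t), n_starts=1))
            wins += best.spec.family is Family.LOGLOGISTIC
        assert wins >= 0.8 * n_rep
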