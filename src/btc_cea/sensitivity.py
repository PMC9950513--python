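"""Deterministic and probabilistic sensitivity analyses.

* One-way analysis (tornado): each parameter is moved to its lower and
  upper bound with everything else at base, the model re-run, and entries
  ranked by the induced ICER span.
* Price-threshold search: bisection on a multiplicative durvalumab price
  factor until the ICER meets a willingness-to-pay target.
* Probabilistic analysis: every uncertain parameter is drawn from its
  assigned class — gamma for costs, beta for probabilities and utilities —
  moment-matched so the mean equals the base value and the central 95%
  interval reproduces the stated range; cost-effectiveness acceptability
  curves report the fraction of draws with positive incremental net
  monetary benefit across a WTP grid.

Survival-model parameters are fixed in the model and excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import FlatParam, ScenarioConfig
from .economics import ScenarioInputs, compute_cea, evaluate_arm
from .markov import CohortTrace, make_arm_trace


def _traces(config: ScenarioConfig) -> dict[str, CohortTrace]:
    """Arm traces are invariant to cost/utility parameters: compute once."""
    settings = config.settings.to_settings()
    specs = config.survival_specs()
    return {arm: make_arm_trace(s["os"], s["pfs"], settings)
            for arm, s in specs.items()}


def _run(config: ScenarioConfig, perspective: str,
         traces: dict[str, CohortTrace],
         overrides: dict[str, float] | None = None,
         inputs: ScenarioInputs | None = None):
    inputs = inputs or config.build_inputs(perspective, overrides)
    arms = {arm: evaluate_arm(arm, tr, inputs) for arm, tr in traces.items()}
    return compute_cea(arms, inputs.wtp, perspective)


# ------------------------------------------------------------------ OWSA

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def owsa(config: ScenarioConfig, perspective: str) -> pd.DataFrame:
    """One-way sensitivity analysis over every ranged parameter.

    Returns a tornado table sorted by descending ICER span with columns
    ``parameter, low, high, icer_low, icer_high, span``.
    """
    traces = _traces(config)
    entries = []
    for p in config.param_index(perspective):
        if p.low > p.base or p.high < p.base:
            raise ValueError(f"invalid range for {p.path}")
        icer_lo = _run(config, perspective, traces, {p.path: p.low}).icer_qaly
        icer_hi = _run(config, perspective, traces, {p.path: p.high}).icer_qaly
        entries.append(TornadoEntry(p.path, p.low, p.high, icer_lo, icer_hi))
    entries.sort(key=lambda e: -e.span)
    return pd.DataFrame(
        [{"parameter": e.parameter, "low": e.low, "high": e.high,
          "icer_low": e.icer_low, "icer_high": e.icer_high, "span": e.span}
         for e in entries]
    )


# ----------------------------------------------------- price threshold

def price_threshold(
    target_icer: float,
    config: ScenarioConfig,
    perspective: str = "us",
    tol: float = 1.0,
) -> float:
    """Durvalumab price reduction (fraction) at which the ICER hits target.

    Bisects a multiplicative price factor in [0, 1] until
    |ICER - target| < ``tol`` dollars; returns 1 - factor.  Raises if the
    base-case ICER is already at/below target is not (reduction would be
    negative) or if the target is unreachable even at price zero.
    """
    traces = _traces(config)
    path = f"costs.{perspective}.drugs.durvalumab"
    base_price = config.costs[perspective].drugs["durvalumab"].value

    def icer_at(mult: float) -> float:
        return _run(config, perspective, traces,
                    {path: base_price * mult}).icer_qaly

    icer_full = icer_at(1.0)
    if icer_full <= target_icer:
        if abs(icer_full - target_icer) <= tol:
            return 0.0
        raise ValueError("base-case ICER is already below the target")
    icer_zero = icer_at(0.0)
    if icer_zero > target_icer:
        raise ValueError(
            f"target unreachable: even at price 0 the ICER is {icer_zero:,.2f}"
        )
    lo, hi = 0.0, 1.0  # icer(lo) <= target <= icer(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        ic = icer_at(mid)
        if abs(ic - target_icer) < tol:
            return 1.0 - mid
        if ic > target_icer:
            hi = mid
        else:
            lo = mid
    return 1.0 - 0.5 * (lo + hi)


# --------------------------------------------------------------- PSA

def _solve_width(width_err, lo, hi, n_grid=60):
    """Root of a (piecewise-monotone) quantile-width residual on a log grid.

    Scans for an adjacent sign change, preferring the right-most bracket
    (the large-parameter branch, where width decreases monotonically)."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([width_err(g) for g in grid])
    for i in range(n_grid - 2, -1, -1):
        if vals[i] == 0.0:
            return grid[i]
        if vals[i] * vals[i + 1] < 0:
            return optimize.brentq(width_err, grid[i], grid[i + 1], xtol=1e-12)
    return None


def fit_gamma(mean: float, low: float, high: float):
    """Gamma with the given mean whose central 95% width matches high - low."""
    width = high - low
    if width <= 0 or mean <= 0:
        return None  # degenerate: treated as fixed

    def width_err(log_shape):
        a = np.exp(log_shape)
        d = stats.gamma(a=a, scale=mean / a)
        return (d.ppf(0.975) - d.ppf(0.025)) - width

    sol = _solve_width(width_err, np.log(0.02), np.log(5e6))
    if sol is None:
        # range too wide/narrow for any gamma at this mean: SD fallback
        warnings.warn(f"gamma moment match infeasible (mean={mean}); "
                      "falling back to range-implied SD")
        sd = width / 3.92
        a = (mean / sd) ** 2
        return stats.gamma(a=a, scale=mean / a)
    a = np.exp(sol)
    return stats.gamma(a=a, scale=mean / a)


def fit_beta(mean: float, low: float, high: float):
    """Beta with the given mean whose central 95% width matches high - low."""
    width = high - low
    if width <= 0:
        return None
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")

    def width_err(log_conc):
        c = np.exp(log_conc)
        d = stats.beta(a=mean * c, b=(1 - mean) * c)
        return (d.ppf(0.975) - d.ppf(0.025)) - width

    sol = _solve_width(width_err, np.log(0.1), np.log(5e7))
    if sol is None:
        warnings.warn(f"beta moment match infeasible (mean={mean}); "
                      "falling back to range-implied SD")
        sd = min(width / 3.92, 0.95 * np.sqrt(mean * (1 - mean)))
        c = mean * (1 - mean) / sd**2 - 1
        c = max(c, 0.2)
        return stats.beta(a=mean * c, b=(1 - mean) * c)
    c = np.exp(sol)
    return stats.beta(a=mean * c, b=(1 - mean) * c)


def param_distribution(p: FlatParam):
    """Frozen sampling distribution for one parameter (None = keep fixed).

    Negative-valued beta-class parameters (AE disutilities) are drawn on
    the magnitude scale and negated.
    """
    if p.dist == "gamma":
        return fit_gamma(p.base, p.low, p.high), 1.0
    if p.dist == "beta":
        if p.base < 0:
            return fit_beta(-p.base, -p.high, -p.low), -1.0
        return fit_beta(p.base, p.low, p.high), 1.0
    return None, 1.0


@dataclass
class PSAResult:
    """Monte-Carlo parameter draws with their incremental outcomes."""

    samples: pd.DataFrame   # columns: d_cost, d_qaly, d_ly + one per parameter
    perspective: str
    wtp: float
    seed: int

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        """P(intervention cost-effective) over a WTP grid: fraction of draws
        with positive incremental net monetary benefit."""
        if wtp_grid is None:
            wtp_grid = np.linspace(0, 500_000, 101)
        dc = self.samples["d_cost"].to_numpy()
        dq = self.samples["d_qaly"].to_numpy()
        prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
        return pd.DataFrame({"wtp": np.asarray(wtp_grid, float),
                             "p_cost_effective": prob})

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        w = self.wtp if wtp is None else wtp
        s = self.samples
        return float((w * s["d_qaly"] - s["d_cost"] > 0).mean())

    def scatter(self) -> pd.DataFrame:
        return self.samples[["d_qaly", "d_cost"]].copy()


def psa(
    config: ScenarioConfig,
    perspective: str,
    n_samples: int = 10_000,
    seed: int = 42,
    sd_scale: float = 1.0,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n_samples`` seeded draws.

    ``sd_scale`` scales every sampling distribution's spread around its
    base value (0 collapses the PSA onto the base case, useful as a
    degeneracy check).  Reproducible: same seed, same draws.
    """
    if n_samples < 100:
        raise ValueError("PSA needs at least 100 samples")
    rng = np.random.default_rng(seed)
    traces = _traces(config)
    params = config.param_index(perspective)
    dists = [param_distribution(p) for p in params]

    draws = np.empty((n_samples, len(params)))
    for j, (p, (dist, sign)) in enumerate(zip(params, dists)):
        if dist is None:
            draws[:, j] = p.base
        else:
            x = sign * dist.rvs(size=n_samples, random_state=rng)
            if sd_scale != 1.0:
                x = p.base + sd_scale * (x - p.base)
            draws[:, j] = x

    rec = []
    for i in range(n_samples):
        overrides = {p.path: draws[i, j] for j, p in enumerate(params)}
        res = _run(config, perspective, traces, overrides)
        rec.append((res.delta_cost, res.delta_qaly, res.delta_ly))
    out = pd.DataFrame(rec, columns=["d_cost", "d_qaly", "d_ly"])
    for j, p in enumerate(params):
        out[p.path] = draws[:, j]
    return PSAResult(out, perspective, config.wtp[perspective], seed)
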