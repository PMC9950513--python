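"""Parametric survival families, right-censored maximum likelihood, and
information-criterion model selection.

Six candidate families are supported for extrapolating trial Kaplan-Meier
data beyond follow-up: exponential, Weibull, gamma, log-normal, log-logistic
and Gompertz.  All times are in **months**.  Parameterisations:

======================  =======================  ===========================
family                  params                   survival function
======================  =======================  ===========================
exponential             rate                     exp(-rate*t)
weibull                 shape, scale             exp(-(t/scale)^shape)
gamma                   shape, rate              1 - P(shape, rate*t)
lognormal               meanlog, sdlog           1 - Phi((ln t - mu)/sigma)
loglogistic             shape, scale             [1 + (t/scale)^shape]^-1
gompertz                shape, rate              exp(-rate/shape*(e^(shape*t)-1))
======================  =======================  ===========================

The log-logistic convention is fixed so that the median equals the scale
parameter.  Gompertz shapes must be strictly positive (a non-positive shape
yields an improper survival distribution and is rejected at construction).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats


class Family(str, Enum):
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"
    GOMPERTZ = "gompertz"


#: parameter names, in order, per family
PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.EXPONENTIAL: ("rate",),
    Family.WEIBULL: ("shape", "scale"),
    Family.GAMMA: ("shape", "rate"),
    Family.LOGNORMAL: ("meanlog", "sdlog"),
    Family.LOGLOGISTIC: ("shape", "scale"),
    Family.GOMPERTZ: ("shape", "rate"),
}

# parameters that must be strictly positive (lognormal meanlog is free)
_POSITIVE = {
    Family.EXPONENTIAL: (True,),
    Family.WEIBULL: (True, True),
    Family.GAMMA: (True, True),
    Family.LOGNORMAL: (False, True),
    Family.LOGLOGISTIC: (True, True),
    Family.GOMPERTZ: (True, True),
}


@dataclass(frozen=True)
class ParametricModelSpec:
    """A fitted (or assumed) survival distribution, time unit = months."""

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        names = PARAM_NAMES[fam]
        if len(p) != len(names):
            raise ValueError(
                f"{fam.value} expects {len(names)} parameters {names}, got {len(p)}"
            )
        for name, val, pos in zip(names, p, _POSITIVE[fam]):
            if not np.isfinite(val):
                raise ValueError(f"{fam.value} {name} must be finite, got {val}")
            if pos and val <= 0:
                raise ValueError(
                    f"{fam.value} {name} must be strictly positive, got {val}"
                )

    # -- scipy frozen distribution --------------------------------------
    @property
    def dist(self):
        f, p = self.family, self.params
        if f is Family.EXPONENTIAL:
            return stats.expon(scale=1.0 / p[0])
        if f is Family.WEIBULL:
            return stats.weibull_min(c=p[0], scale=p[1])
        if f is Family.GAMMA:
            return stats.gamma(a=p[0], scale=1.0 / p[1])
        if f is Family.LOGNORMAL:
            return stats.lognorm(s=p[1], scale=np.exp(p[0]))
        if f is Family.LOGLOGISTIC:
            return stats.fisk(c=p[0], scale=p[1])
        if f is Family.GOMPERTZ:
            shape, rate = p
            return stats.gompertz(c=rate / shape, scale=1.0 / shape)
        raise AssertionError(f)

    @property
    def named_params(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def survival(self, t):
        """S(t) for t >= 0 (scalar or array), values in [0, 1]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival is defined for t >= 0 only")
        return self.dist.sf(t)

    def density(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("density is defined for t >= 0 only")
        return self.dist.pdf(t)

    def hazard(self, t):
        """h(t) = f(t)/S(t) wherever S(t) > 0."""
        s = self.survival(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, self.density(t) / s, np.inf)

    def median(self) -> float:
        return float(self.dist.median())

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.dist.rvs(size=n, random_state=rng)

    def loglik(self, times, events) -> float:
        """Right-censored log-likelihood: sum ln f over events + ln S over censored."""
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        d = self.dist
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(d.logpdf(times[events])) + np.sum(d.logsf(times[~events]))
        return float(ll)


def survival_at(spec: ParametricModelSpec, t) -> float | np.ndarray:
    """Survival probability S(t); thin functional wrapper over the spec."""
    out = spec.survival(t)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to right-censored data.

    aic = 2k - 2 loglik, bic = k ln(n) - 2 loglik with k = number of params.
    """

    spec: ParametricModelSpec
    loglik: float
    n: int
    converged: bool
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.spec.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.loglik

    def to_record(self) -> dict:
        return {
            "family": self.spec.family.value,
            "params": self.spec.named_params,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "converged": self.converged,
        }


def _moment_start(times, events, family: Family) -> np.ndarray:
    """Crude moment-based starting values on the natural scale."""
    t_ev = times[events]
    m = float(np.mean(t_ev))
    med = float(np.median(t_ev))
    sd = float(np.std(t_ev)) or m / 2 or 1.0
    m = m or 1.0
    if family is Family.EXPONENTIAL:
        return np.array([1.0 / m])
    if family is Family.WEIBULL:
        return np.array([1.2, m])
    if family is Family.GAMMA:
        shape = max((m / sd) ** 2, 0.2)
        return np.array([shape, shape / m])
    if family is Family.LOGNORMAL:
        lt = np.log(np.maximum(t_ev, 1e-8))
        return np.array([float(np.mean(lt)), max(float(np.std(lt)), 0.1)])
    if family is Family.LOGLOGISTIC:
        return np.array([1.5, max(med, 1e-3)])
    if family is Family.GOMPERTZ:
        return np.array([0.1, 1.0 / m])
    raise AssertionError(family)


def fit_mle(
    times: Sequence[float],
    events: Sequence[int],
    family: Family | str,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> FitResult:
    """Fit one family by maximum likelihood under right censoring.

    Parameters are optimised in log space (meanlog excepted) with
    multi-start Nelder-Mead followed by a gradient polish.  The exponential
    family uses its closed form, rate = events / sum(t).

    Raises ``ValueError`` on all-censored input ("no events") or fewer than
    two distinct event times for multi-parameter families.
    """
    family = Family(family)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-d and the same length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    n = times.size
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events: cannot fit a survival model to fully censored data")
    if family is not Family.EXPONENTIAL and np.unique(times[events]).size < 2:
        raise ValueError("need at least 2 distinct event times")

    if family is Family.EXPONENTIAL:
        rate = n_events / float(times.sum())
        spec = ParametricModelSpec(family, (rate,))
        return FitResult(spec, spec.loglik(times, events), n, True, "closed form")

    free_sign = _POSITIVE[family]  # which params live on log scale

    def to_natural(z):
        return np.array(
            [np.exp(v) if pos else v for v, pos in zip(z, free_sign)]
        )

    def to_working(p):
        return np.array(
            [np.log(v) if pos else v for v, pos in zip(p, free_sign)]
        )

    # guard event time 0 for families whose density vanishes/diverges there
    tfit = np.where((times == 0) & events, 1e-6, times)

    def nll(z):
        try:
            spec = ParametricModelSpec(family, tuple(to_natural(z)))
        except (ValueError, OverflowError):
            return 1e12
        ll = spec.loglik(tfit, events)
        return -ll if np.isfinite(ll) else 1e12

    base = _moment_start(tfit, events, family)
    starts = [to_working(base)]
    for fac in (0.5, 2.0):
        starts.append(to_working(np.maximum(base * fac, 1e-6)))
    starts = starts[:n_starts]

    best = None
    for z0 in starts:
        res = optimize.minimize(
            nll, z0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # gradient polish from the best vertex
    polish = optimize.minimize(nll, best.x, method="BFGS",
                               options={"gtol": 1e-7, "maxiter": 200})
    if polish.fun <= best.fun:
        best = polish
    params = tuple(to_natural(best.x))
    spec = ParametricModelSpec(family, params)
    ll = spec.loglik(tfit, events)
    converged = bool(np.isfinite(ll)) and best.fun < 1e11
    return FitResult(spec, ll, n, converged, str(best.message))


def fit_all(times, events, families: Iterable[Family | str] = tuple(Family),
            **fit_kwargs) -> list[FitResult]:
    """Fit every requested family to the same data; skips families that error."""
    out = []
    for fam in families:
        try:
            out.append(fit_mle(times, events, fam, **fit_kwargs))
        except ValueError as exc:  # e.g. ties insufficient for this family
            warnings.warn(f"skipping {fam}: {exc}")
    if not out:
        raise ValueError("no family could be fitted")
    return out


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Pick the fit with minimal AIC; ties broken by BIC, then fewest params."""
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires a non-empty list of fits")
    return min(fits, key=lambda f: (round(f.aic, 10), round(f.bic, 10), f.k))


# -- delimited-text IPD I/O ---------------------------------------------

def write_ipd(path, times, events) -> None:
    """Write `time,event` CSV (event in {0,1})."""
    import pandas as pd

    pd.DataFrame({"time": times, "event": np.asarray(events, dtype=int)}).to_csv(
        path, index=False
    )


def read_ipd(path) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    return df["time"].to_numpy(float), df["event"].to_numpy(int)


def write_fit_records(path, fits: Sequence[FitResult]) -> None:
    Path(path).write_text(json.dumps([f.to_record() for f in fits], indent=2))
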