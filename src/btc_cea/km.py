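"""Kaplan-Meier estimation and recovery of pseudo individual patient data
(IPD) from digitized survival curves plus numbers-at-risk tables.

The reconstruction follows the Guyot approach: within each numbers-at-risk
interval the censoring count is solved iteratively so that the implied
at-risk count at the next interval boundary matches the published number,
with censoring times spread uniformly across the interval; event counts at
each digitized coordinate come from the Kaplan-Meier drops.  The algorithm
is deterministic: identical inputs yield identical IPD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) coordinates of one arm's KM curve."""

    times: np.ndarray
    surv: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and surv must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any((s < -1e-9) | (s > 1 + 1e-9)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        s = np.clip(s, 0.0, 1.0)
        if t[0] > 0:  # anchor at (0, 1)
            t = np.insert(t, 0, 0.0)
            s = np.insert(s, 0, 1.0)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", s)

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.surv) <= 1e-12))

    def cleaned(self) -> "DigitizedCurve":
        """Snap digitization jitter: running-minimum (isotonic) clamp."""
        if self.is_monotone:
            return self
        warnings.warn("digitized curve not non-increasing; clamping jitter")
        return DigitizedCurve(self.times, np.minimum.accumulate(self.surv), self.label)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.surv}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(float), df["survival"].to_numpy(float), label)


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at published interval boundaries."""

    times: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        if t.ndim != 1 or t.shape != n.shape or t.size == 0:
            raise ValueError("times and n_risk must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("numbers at risk must be non-negative")
        if np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk may not increase over time")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_risk", n)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "n_risk": self.n_risk}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(float), df["n_risk"].to_numpy(int))


@dataclass(frozen=True)
class ReconstructedIPD:
    """Per-subject (time, event) pairs; event=1 death/progression, 0 censored."""

    times: np.ndarray
    events: np.ndarray
    label: str = ""
    meta: dict | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "event": self.events}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ReconstructedIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(int), label)


def km_estimate(ipd: ReconstructedIPD, at_times=None) -> DigitizedCurve:
    """Product-limit survival estimate of an IPD sample.

    Returns the step function evaluated just after each unique event time
    (or at ``at_times`` when given).  Requires at least one event.
    """
    if ipd.n == 0:
        raise ValueError("cannot estimate a KM curve from an empty sample")
    if ipd.n_events == 0:
        raise ValueError("cannot estimate a KM curve without any events")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    if at_times is None:
        at_times = np.unique(ipd.times[ipd.events == 1])
    at_times = np.asarray(at_times, dtype=float)
    surv = kmf.survival_function_at_times(at_times).to_numpy()
    return DigitizedCurve(at_times, surv, ipd.label)


def _km_value(curve: DigitizedCurve, t: float) -> float:
    """Step-function lookup of the digitized curve at time t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.surv[max(idx, 0)])


def guyot_reconstruct(
    curve: DigitizedCurve,
    risk: RiskTable | None,
    total_events: int | None = None,
    max_iter: int = 40,
) -> ReconstructedIPD:
    """Recover pseudo-IPD from a digitized KM curve and a risk table.

    When ``risk`` is None the no-censoring variant is used: the curve drops
    are converted directly to event counts out of the initial cohort (whose
    size must then be supplied via a one-row risk table is impossible, so
    ``total_events`` doubles as the arm size).  When ``total_events`` is
    given alongside a risk table, censoring in the final interval is tuned
    so the reconstructed event count matches it as closely as possible.
    """
    curve = curve.cleaned()
    t = curve.times
    s = curve.surv
    K = t.size

    if risk is None:
        if total_events is None:
            raise ValueError("without a risk table, total_events (= arm size) is required")
        n0 = int(total_events)
        d = np.zeros(K, dtype=int)
        n_at = n0
        km_prev = 1.0
        for k in range(1, K):
            if km_prev <= 0 or n_at <= 0:
                break
            dk = int(round(n_at * (1.0 - s[k] / km_prev)))
            dk = min(max(dk, 0), n_at)
            if dk > 0:
                km_prev *= 1.0 - dk / n_at
                n_at -= dk
                d[k] = dk
        times, events = _assemble(t, d, [], n_at)
        return ReconstructedIPD(times, events, curve.label, {"censoring": "none"})

    if risk.times[0] > t[0] or risk.times[-1] > t[-1] + 1e-9:
        raise ValueError("risk-table boundaries must lie within the digitized time span")

    n_total = int(risk.n_risk[0])
    bounds = list(risk.times) + [t[-1] + 1e-9]
    # digitized indices in [lower_i, upper_i) per risk interval; a coordinate
    # exactly on a boundary belongs to the earlier interval (its drop is
    # still reflected in the number at risk printed at that boundary)
    lowers = [int(np.searchsorted(t, b, side="right")) for b in bounds[:-1]]
    lowers[0] = 0
    uppers = lowers[1:] + [K]

    d = np.zeros(K, dtype=int)  # events at each coordinate
    cen_times: list[float] = []
    n_at = n_total
    km_prev = 1.0

    for i in range(len(lowers)):
        lo, up = lowers[i], uppers[i]
        last = i == len(lowers) - 1
        n_target = None if last else int(risk.n_risk[i + 1])
        s_lo = _km_value(curve, bounds[i])
        s_hi = _km_value(curve, bounds[i + 1] - 1e-12)
        if last:
            ncen = 0
        else:
            guess = n_at * (s_hi / s_lo if s_lo > 0 else 0.0) - n_target
            ncen = int(round(max(guess, 0)))

        state = None
        for _ in range(max_iter):
            state = _walk_interval(
                t, s, lo, up, bounds[i], bounds[i + 1], n_at, km_prev, ncen
            )
            if last or state["n_end"] == n_target:
                break
            ncen = max(ncen + state["n_end"] - n_target, 0)
        d[lo:up] = state["d"]
        cen_times.extend(state["cen_times"])
        n_at = state["n_end"]
        km_prev = state["km"]

    # optional event-total adjustment: trade final-interval censoring
    if total_events is not None and d.sum() != total_events:
        d, n_at, cen_times = _adjust_total_events(
            t, s, lowers[-1], K, bounds[-2], bounds[-1], risk, d, cen_times,
            total_events, max_iter,
        )

    times, events = _assemble(t, d, cen_times, n_at)
    return ReconstructedIPD(times, events, curve.label, {"censoring": "uniform-in-interval"})


def _walk_interval(t, s, lo, up, t_lo, t_hi, n_start, km_start, ncen):
    """Step through one risk interval with ``ncen`` uniformly-spread censorings."""
    width = t_hi - t_lo
    cen = [t_lo + (j + 1) * width / (ncen + 1) for j in range(ncen)]
    cen_used: list[float] = []
    d = np.zeros(up - lo, dtype=int)
    n_at = n_start
    km = km_start
    ci = 0
    for k in range(lo, up):
        if t[k] <= t_lo and km_start == km and t[k] == 0:
            continue  # the (0,1) anchor carries no information
        if n_at > 0 and km > 0:
            dk = int(round(n_at * (1.0 - s[k] / km)))
            dk = min(max(dk, 0), n_at)
            if dk > 0:
                km *= 1.0 - dk / n_at
                n_at -= dk
                d[k - lo] = dk
        # censor all scheduled times up to the next coordinate
        t_next = t[k + 1] if k + 1 < up else t_hi
        while ci < ncen and cen[ci] <= t_next and n_at > 0:
            cen_used.append(cen[ci])
            n_at -= 1
            ci += 1
    return {"d": d, "cen_times": cen_used, "n_end": n_at, "km": km}


def _adjust_total_events(t, s, lo, up, t_lo, t_hi, risk, d, cen_times,
                         total_events, max_iter):
    """Re-walk the final interval over a range of censor counts, choosing the
    count whose reconstructed event total is closest to the published one."""
    events_before = int(d[:lo].sum())
    # state entering the last interval
    n_enter = int(risk.n_risk[-1])
    km_enter = None
    # recompute km at interval start from events so far
    km_enter = 1.0
    n_at = int(risk.n_risk[0])
    for k in range(lo):
        if d[k] > 0:
            km_enter *= 1.0 - d[k] / n_at
            n_at -= d[k]
    # censoring before the last interval
    n_cen_before = len([c for c in cen_times if c <= t_lo + 1e-12])
    n_enter = int(risk.n_risk[0]) - events_before - n_cen_before

    best = None
    for ncen in range(0, n_enter + 1):
        state = _walk_interval(t, s, lo, up, t_lo, t_hi, n_enter, km_enter, ncen)
        tot = events_before + int(state["d"].sum())
        miss = abs(tot - total_events)
        if best is None or miss < best[0]:
            best = (miss, ncen, state)
        if miss == 0:
            break
    _, _, state = best
    d = d.copy()
    d[lo:up] = state["d"]
    cen_keep = [c for c in cen_times if c <= t_lo + 1e-12]
    return d, state["n_end"], cen_keep + state["cen_times"]


def _assemble(t, d, cen_times, n_leftover):
    """Build per-subject arrays: events at coordinates, censors at their
    times, leftovers administratively censored at the last coordinate."""
    times = []
    events = []
    for k in range(t.size):
        times.extend([t[k]] * int(d[k]))
        events.extend([1] * int(d[k]))
    times.extend(cen_times)
    events.extend([0] * len(cen_times))
    times.extend([t[-1]] * int(n_leftover))
    events.extend([0] * int(n_leftover))
    return np.asarray(times, dtype=float), np.asarray(events, dtype=int)
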