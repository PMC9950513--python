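"""Synthetic trial data with known ground truth.

Emulates a two-arm first-line trial of durvalumab + gemcitabine/cisplatin
vs gemcitabine/cisplatin in advanced biliary tract cancer (arm sizes 198
and 226): per-subject progression and death times drawn from the arm's
parametric PFS/OS models, administrative censoring from uniform accrual
against a fixed data cutoff, and a "digitization" step that samples the KM
curve on a grid with optional jitter, mimicking hand-extraction of points
from a published figure.

Progression and death draws are independent (only marginal curves are
available from a published trial); per-subject PFS time is the minimum of
the progression draw and the death draw, so PFS <= OS always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .km import DigitizedCurve, ReconstructedIPD, RiskTable, km_estimate
from .survival import Family, ParametricModelSpec


def default_arms() -> dict[str, dict[str, ParametricModelSpec]]:
    """The fitted trial survival models used as simulation ground truth."""
    return {
        "durva": {
            "os": ParametricModelSpec(Family.LOGLOGISTIC, (1.81, 13.55)),
            "pfs": ParametricModelSpec(Family.LOGLOGISTIC, (2.19, 7.07)),
        },
        "chemo": {
            "os": ParametricModelSpec(Family.LOGLOGISTIC, (2.22, 11.68)),
            "pfs": ParametricModelSpec(Family.GAMMA, (2.76, 0.38)),
        },
    }


@dataclass(frozen=True)
class TrialSimSpec:
    """Simulation scenario: arm sizes, survival truth, censoring, digitization.

    Accrual is uniform over ``accrual_months``; a subject enrolled at offset
    a is administratively censored at ``cutoff_months - a`` of follow-up.
    """

    n_per_arm: dict = field(default_factory=lambda: {"durva": 198, "chemo": 226})
    models: dict = field(default_factory=default_arms)
    accrual_months: float = 12.0
    cutoff_months: float = 24.0
    grid_size: int = 60
    grid_max_months: float = 24.0
    jitter_sd: float = 0.005
    n_risk_times: int = 6
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_arm.values()):
            raise ValueError("arm sizes must be positive")
        if self.cutoff_months <= 0:
            raise ValueError("data cutoff must be positive")
        if not 0 <= self.accrual_months < self.cutoff_months + 1e12:
            raise ValueError("accrual window must be non-negative")


def simulate_ipd(spec: TrialSimSpec) -> dict[str, dict[str, ReconstructedIPD]]:
    """Draw per-subject OS and PFS IPD for every arm; bit-reproducible by seed.

    Returns ``{arm: {"os": ipd, "pfs": ipd}}``.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict[str, ReconstructedIPD]] = {}
    for arm in sorted(spec.n_per_arm):
        n = int(spec.n_per_arm[arm])
        t_death = spec.models[arm]["os"].rvs(n, rng)
        t_prog = spec.models[arm]["pfs"].rvs(n, rng)
        t_pfs = np.minimum(t_prog, t_death)  # progression-free = first of the two
        accrual = rng.uniform(0.0, spec.accrual_months, size=n)
        followup = np.maximum(spec.cutoff_months - accrual, 0.0)
        out[arm] = {}
        for name, true_t in (("os", t_death), ("pfs", t_pfs)):
            event = (true_t <= followup).astype(int)
            obs = np.minimum(true_t, followup)
            out[arm][name] = ReconstructedIPD(obs, event, f"{arm}-{name}")
    return out


def digitize(
    ipd: ReconstructedIPD,
    grid: np.ndarray | None = None,
    jitter_sd: float = 0.005,
    n_risk_times: int = 6,
    seed: int = 0,
) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate figure digitization: KM sampled on a grid plus Gaussian jitter.

    The risk table is exact (trial reports print true numbers at risk):
    counts of subjects still under observation at each of ``n_risk_times``
    evenly spaced times starting at 0.
    """
    if ipd.n == 0:
        raise ValueError("cannot digitize an empty sample")
    if grid is None:
        grid = np.linspace(0.0, float(ipd.times.max()), 60)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 0:
        grid = np.insert(grid, 0, 0.0)
    # a careful digitizer always clicks the curve at the printed
    # numbers-at-risk times; reconstruction relies on those anchors
    risk_t = np.linspace(0.0, float(grid[-1]), n_risk_times, endpoint=False)
    grid = np.unique(np.concatenate([grid, risk_t]))
    km = km_estimate(ipd, at_times=grid)
    surv = km.surv.copy()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter_sd, size=surv.size)
        noise[0] = 0.0  # the anchor (0, 1) is never misread
        surv = np.clip(surv + noise, 0.0, 1.0)
    curve = DigitizedCurve(grid, surv, ipd.label)

    risk_t = np.linspace(0.0, float(grid[-1]), n_risk_times, endpoint=False)
    n_risk = np.array([(ipd.times >= rt - 1e-12).sum() for rt in risk_t], dtype=int)
    return curve, RiskTable(risk_t, n_risk)


def simulate_and_digitize(spec: TrialSimSpec):
    """Full synthetic pipeline input: IPD plus digitized curve + risk table
    per arm/endpoint, with independent jitter seeds per curve."""
    ipd = simulate_ipd(spec)
    digitized = {}
    sub = 0
    for arm in sorted(ipd):
        digitized[arm] = {}
        for name in ("os", "pfs"):
            sub += 1
            grid = np.linspace(0.0, spec.grid_max_months, spec.grid_size)
            digitized[arm][name] = digitize(
                ipd[arm][name], grid, spec.jitter_sd, spec.n_risk_times,
                seed=spec.seed * 1000 + sub,
            )
    return ipd, digitized
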