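"""Cost and utility layer on top of the cohort trace, and incremental
cost-effectiveness statistics.

Costing conventions (all monetary values 2021 USD, per 21-day cycle unless
one-time):

* progression-free (PFS) state: first-line drug acquisition while on
  treatment (gemcitabine/cisplatin up to a cycle cap; durvalumab, in the
  intervention arm, up to a duration cap), plus routine follow-up
  (laboratory, imaging, bed, care);
* first cycle only: one-time first-hospitalisation laboratory + imaging
  work-up and the expected one-time cost and QALY decrement of grade >= 3
  adverse events (risk-weighted);
* progressed disease (PD) state: PD follow-up costs, plus the expected
  per-cycle cost of subsequent (second-line) therapy — a mixture over
  chemotherapy (FOLFOX), targeted therapy (regorafenib), immunotherapy
  (durvalumab) and other (irinotecan + capecitabine) — charged only while
  a patient's PD tenure is below a configurable number of cycles;
* death: zero.

Recurring costs use half-cycle-corrected occupancy; one-time costs are
charged at model start undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import CohortTrace, ModelSettings

# adverse-event risk keys <-> disutility keys (trial AE terms vs utility
# literature terms for the same toxicities)
AE_DISUTILITY_KEY = {
    "neutrophil_count_decreased": "leukopenia",
    "neutropenia": "neutropenia",
    "anemia": "anemia",
    "platelet_count_decreased": "thrombocytopenia",
}

STATES = ("pfs", "pd", "death")
ARMS = ("durva", "chemo")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and adverse-event disutilities."""

    u_pfs: float = 0.76
    u_pd: float = 0.68
    disutilities: dict = field(default_factory=lambda: {
        "leukopenia": -0.09,
        "anemia": -0.125,
        "neutropenia": -0.09,
        "thrombocytopenia": -0.20,
    })
    #: duration a one-time AE disutility is assumed to last, in years
    ae_duration_years: float = 1.0

    def __post_init__(self):
        for name, u in (("u_pfs", self.u_pfs), ("u_pd", self.u_pd)):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")
        for k, d in self.disutilities.items():
            if not -1.0 <= d <= 0.0:
                raise ValueError(f"disutility {k} must lie in [-1, 0], got {d}")


@dataclass(frozen=True)
class CostInputs:
    """One payer perspective's unit costs."""

    drugs: dict            # drug -> $ per cycle
    followup: dict         # lab/imaging (first, pfs, pd), bed, care -> $ per cycle
    ae_costs: dict         # AE -> one-time $

    def __post_init__(self):
        for group in (self.drugs, self.followup, self.ae_costs):
            for k, v in group.items():
                if v < 0:
                    raise ValueError(f"cost {k} must be non-negative, got {v}")

    @property
    def first_visit(self) -> float:
        return self.followup["lab_first"] + self.followup["imaging_first"]

    def state_followup(self, state: str) -> float:
        fu = self.followup
        if state == "pfs":
            return fu["lab_pfs"] + fu["imaging_pfs"] + fu["bed"] + fu["care"]
        if state == "pd":
            return fu["lab_pd"] + fu["imaging_pd"] + fu["bed"] + fu["care"]
        return 0.0


@dataclass(frozen=True)
class AEProfile:
    """Grade >= 3 adverse-event risks per arm."""

    risks: dict  # arm -> {ae -> probability}

    def __post_init__(self):
        for arm, rr in self.risks.items():
            for k, p in rr.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"AE risk {arm}.{k} must lie in [0,1], got {p}")


@dataclass(frozen=True)
class SubsequentTherapyMix:
    """Second-line uptake proportions and regimen -> drug mapping."""

    proportions: dict  # arm -> {category -> proportion}
    regimens: dict = field(default_factory=lambda: {
        "chemotherapy": ["oxaliplatin", "calcium_folinate", "fluorouracil"],
        "targeted": ["regorafenib"],
        "immunotherapy": ["durvalumab"],
        "other": ["irinotecan", "capecitabine"],
    })
    max_cycles: int = 6

    def __post_init__(self):
        for arm, props in self.proportions.items():
            for k, p in props.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"proportion {arm}.{k} out of [0,1]: {p}")
            if sum(props.values()) > 1.0 + 1e-9:
                raise ValueError(f"subsequent-therapy proportions for {arm} exceed 1")

    def expected_cycle_cost(self, arm: str, drugs: dict) -> float:
        return sum(
            p * sum(drugs[d] for d in self.regimens[cat])
            for cat, p in self.proportions[arm].items()
        )


@dataclass(frozen=True)
class TreatmentRules:
    """On-treatment duration rules for the first-line regimen."""

    gp_max_cycles: int = 8          # gemcitabine/cisplatin cycles (trial regimen)
    durva_max_months: float = 36.0  # durvalumab: until progression, capped

    def durva_max_cycles(self, settings: ModelSettings) -> int:
        return int(round(self.durva_max_months / settings.cycle_months))


@dataclass(frozen=True)
class ScenarioInputs:
    """Everything needed to evaluate both strategies under one perspective."""

    settings: ModelSettings
    utilities: UtilityInputs
    costs: CostInputs
    ae: AEProfile
    mix: SubsequentTherapyMix
    rules: TreatmentRules
    wtp: float
    perspective: str = ""

    def arm_drug_cost(self, arm: str, cycle: int) -> float:
        """First-line drug acquisition cost for a PFS patient at a cycle."""
        c = 0.0
        if cycle < self.rules.gp_max_cycles:
            c += self.costs.drugs["gemcitabine"] + self.costs.drugs["cisplatin"]
        if arm == "durva" and cycle < self.rules.durva_max_cycles(self.settings):
            c += self.costs.drugs["durvalumab"]
        return c


def cycle_cost(state: str, arm: str, cycle: int, scenario: ScenarioInputs,
               include_subsequent: bool = True) -> float:
    """Per-cycle cost for one patient occupying ``state`` at ``cycle``.

    The PD subsequent-therapy component assumes the patient is within the
    subsequent-therapy tenure cap; cohort aggregation weights it by the
    tenure-limited occupancy instead.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if state == "death":
        return 0.0
    if state == "pfs":
        c = scenario.arm_drug_cost(arm, cycle) + scenario.costs.state_followup("pfs")
        if cycle == 0:
            c += scenario.costs.first_visit
        return c
    if state == "pd":
        c = scenario.costs.state_followup("pd")
        if include_subsequent:
            c += scenario.mix.expected_cycle_cost(arm, scenario.costs.drugs)
        return c
    raise ValueError(f"unknown state {state!r}")


def ae_burden(arm: str, scenario: ScenarioInputs) -> tuple[float, float]:
    """Expected one-time AE cost and QALY decrement for an arm.

    cost = sum_i risk_i * unit_cost_i;
    decrement = sum_i risk_i * |disutility_i| * assumed duration (years).
    """
    risks = scenario.ae.risks[arm]
    cost = sum(p * scenario.costs.ae_costs[k] for k, p in risks.items())
    dec = sum(
        p * abs(scenario.utilities.disutilities[AE_DISUTILITY_KEY[k]])
        for k, p in risks.items()
    ) * scenario.utilities.ae_duration_years
    return float(cost), float(dec)


@dataclass(frozen=True)
class ArmResult:
    arm: str
    cost: float
    ly: float
    qaly: float
    breakdown: dict


def evaluate_arm(arm: str, trace: CohortTrace, scenario: ScenarioInputs) -> ArmResult:
    """Accumulate discounted costs and effects for one arm over its trace."""
    st = scenario.settings
    df = trace.df
    k = df["cycle"].to_numpy()
    dy = st.cycle_years
    disc_c = (1.0 + st.discount_cost) ** (-(k + 0.5) * dy)
    pfs_mid = df["pfs_mid"].to_numpy()
    pd_mid = df["pd_mid"].to_numpy()
    de = df["disc_eff"].to_numpy()

    # effect-discounted person-years by state
    e_pfs = float(np.sum(de * pfs_mid) * dy)
    e_pd = float(np.sum(de * pd_mid) * dy)
    u = scenario.utilities
    ae_cost, ae_dec = ae_burden(arm, scenario)
    ly = e_pfs + e_pd
    qaly = u.u_pfs * e_pfs + u.u_pd * e_pd - ae_dec

    # cost-discounted person-cycles
    drug = float(np.sum(disc_c * pfs_mid *
                        np.array([scenario.arm_drug_cost(arm, int(i)) for i in k])))
    fu = float(np.sum(disc_c * pfs_mid) * scenario.costs.state_followup("pfs")
               + np.sum(disc_c * pd_mid) * scenario.costs.state_followup("pd"))
    sub_occ = _tenure_limited_pd(df, st, scenario.mix.max_cycles)
    sub = scenario.mix.expected_cycle_cost(arm, scenario.costs.drugs) * float(
        np.sum(disc_c * sub_occ))
    first = scenario.costs.first_visit
    total = drug + fu + sub + first + ae_cost
    return ArmResult(arm, total, ly, qaly, {
        "first_line_drugs": drug, "followup": fu, "subsequent_therapy": sub,
        "first_visit": first, "adverse_events": ae_cost,
        "e_pfs": e_pfs, "e_pd": e_pd, "ae_decrement": ae_dec,
    })


def _tenure_limited_pd(df: pd.DataFrame, settings: ModelSettings,
                       max_cycles: int) -> np.ndarray:
    """Half-cycle-corrected PD occupancy restricted to tenure < max_cycles.

    New PD entrants start a tenure clock; survivors advance one tenure
    cycle per model cycle (deaths hit all tenures proportionally)."""
    n = len(df)
    entrants = df["pd_entrants"].to_numpy()
    p_death = df["p_pd_death"].to_numpy()
    ten = np.zeros(max_cycles)
    out = np.zeros(n)
    for i in range(n):
        ten_new = np.zeros(max_cycles)
        ten_new[1:] = ten[:-1] * (1.0 - p_death[i])
        ten_new[0] = entrants[i]
        if settings.half_cycle:
            out[i] = 0.5 * (ten.sum() + ten_new.sum())
        else:
            out[i] = ten.sum()
        ten = ten_new
    return out


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy totals and incremental statistics at one WTP."""

    perspective: str
    wtp: float
    arms: dict            # arm -> ArmResult
    intervention: str = "durva"
    comparator: str = "chemo"

    @property
    def delta_cost(self) -> float:
        return self.arms[self.intervention].cost - self.arms[self.comparator].cost

    @property
    def delta_ly(self) -> float:
        return self.arms[self.intervention].ly - self.arms[self.comparator].ly

    @property
    def delta_qaly(self) -> float:
        return self.arms[self.intervention].qaly - self.arms[self.comparator].qaly

    @property
    def icer_qaly(self) -> float | None:
        """ICER per QALY from unrounded internals; None when dQALY = 0."""
        return self.delta_cost / self.delta_qaly if self.delta_qaly != 0 else None

    @property
    def icer_ly(self) -> float | None:
        return self.delta_cost / self.delta_ly if self.delta_ly != 0 else None

    @property
    def dominance(self) -> str:
        dc, dq = self.delta_cost, self.delta_qaly
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq < 0 and dc >= 0:
            return "dominated"
        if dq == 0:
            return "undefined (no QALY difference)"
        return "trade-off"

    def nmb(self, arm: str) -> float:
        a = self.arms[arm]
        return self.wtp * a.qaly - a.cost

    @property
    def incremental_nmb(self) -> float:
        return self.nmb(self.intervention) - self.nmb(self.comparator)

    def to_table(self) -> pd.DataFrame:
        """Base-case table: one row per strategy with incremental columns."""
        rows = []
        for arm in (self.comparator, self.intervention):
            a = self.arms[arm]
            inc = arm == self.intervention
            rows.append({
                "strategy": arm,
                "cost": round(a.cost, 2),
                "incr_cost": round(self.delta_cost, 2) if inc else None,
                "ly": round(a.ly, 2),
                "incr_ly": round(self.delta_ly, 2) if inc else None,
                "icer_per_ly": round(self.icer_ly, 2) if inc and self.icer_ly else None,
                "qaly": round(a.qaly, 2),
                "incr_qaly": round(self.delta_qaly, 2) if inc else None,
                "icer_per_qaly": (round(self.icer_qaly, 2)
                                  if inc and self.icer_qaly else None),
            })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "perspective": self.perspective,
            "wtp": self.wtp,
            "arms": {a: {"cost": r.cost, "ly": r.ly, "qaly": r.qaly,
                         "breakdown": r.breakdown}
                     for a, r in self.arms.items()},
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_qaly": self.icer_qaly,
            "icer_per_ly": self.icer_ly,
            "incremental_nmb": self.incremental_nmb,
            "dominance": self.dominance,
        }


def compute_cea(arm_results: dict[str, ArmResult], wtp: float,
                perspective: str = "", intervention: str = "durva",
                comparator: str = "chemo") -> CEAResult:
    """Incremental cost-effectiveness statistics for two evaluated strategies."""
    if intervention not in arm_results or comparator not in arm_results:
        raise ValueError("both strategies must be present in arm_results")
    return CEAResult(perspective, float(wtp), dict(arm_results),
                     intervention, comparator)
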