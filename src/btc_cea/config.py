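"""Scenario configuration: schema validation, bundled defaults, and the
bridge from a structured-text (YAML) file to the in-memory model inputs.

Every varied parameter carries ``value`` plus an uncertainty block
(``low``/``high``/``dist``) used by the one-way and probabilistic
sensitivity analyses; survival-model parameters are fixed in the model and
excluded from both.  The bundled ``topaz1.yaml`` scenario carries both the
US and the Chinese payer cost blocks; the perspective is selected when
building inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .economics import (
    AEProfile,
    CostInputs,
    ScenarioInputs,
    SubsequentTherapyMix,
    TreatmentRules,
    UtilityInputs,
)
from .markov import ModelSettings
from .survival import Family, ParametricModelSpec

PERSPECTIVES = ("us", "china")


class Param(BaseModel):
    """A scalar input with its sensitivity range and PSA distribution class."""

    model_config = ConfigDict(extra="forbid")

    value: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: Literal["beta", "gamma", "fixed"] = "fixed"

    @model_validator(mode="after")
    def _ordered(self):
        if self.low is not None and self.high is not None:
            if not (self.low <= self.value <= self.high):
                raise ValueError(
                    f"range must satisfy low <= value <= high, got "
                    f"({self.low}, {self.value}, {self.high})"
                )
        return self


class CostParam(Param):
    @field_validator("value")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError(f"cost must be non-negative, got {v}")
        return v


class SurvivalModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: str
    params: list[float]

    def spec(self) -> ParametricModelSpec:
        return ParametricModelSpec(Family(self.family), tuple(self.params))


class ArmSurvival(BaseModel):
    model_config = ConfigDict(extra="forbid")
    os: SurvivalModel
    pfs: SurvivalModel


class SettingsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_cost: float = 0.03
    discount_effect: float = 0.05
    half_cycle: bool = True
    transition_method: str = "pd_exit"
    weight_kg: float = 60.0

    def to_settings(self) -> ModelSettings:
        return ModelSettings(
            cycle_days=self.cycle_days,
            horizon_years=self.horizon_years,
            discount_cost=self.discount_cost,
            discount_effect=self.discount_effect,
            half_cycle=self.half_cycle,
            transition_method=self.transition_method,
            weight_kg=self.weight_kg,
        )


class UtilityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pfs: Param
    pd: Param
    ae_duration_years: float = 1.0


class AEBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    risks: dict[str, dict[str, Param]]
    costs: dict[str, CostParam]


class PerspectiveCosts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drugs: dict[str, CostParam]


class SubsequentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_cycles: int = 6
    proportions: dict[str, dict[str, Param]]
    regimens: dict[str, list[str]] = {
        "chemotherapy": ["oxaliplatin", "calcium_folinate", "fluorouracil"],
        "targeted": ["regorafenib"],
        "immunotherapy": ["durvalumab"],
        "other": ["irinotecan", "capecitabine"],
    }


class TreatmentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gp_max_cycles: int = 8
    durvalumab_max_months: float = 36.0


class ScenarioConfig(BaseModel):
    """Validated scenario file: every tabulated input for both payers."""

    model_config = ConfigDict(extra="forbid")

    settings: SettingsBlock
    survival: dict[str, ArmSurvival]
    utilities: UtilityBlock
    disutilities: dict[str, Param]
    ae: AEBlock
    costs: dict[str, PerspectiveCosts]
    followup: dict[str, CostParam]
    subsequent_therapy: SubsequentBlock
    treatment: TreatmentBlock
    wtp: dict[str, float]

    # ---------------------------------------------------------------- I/O
    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    @classmethod
    def bundled(cls, name: str = "topaz1") -> "ScenarioConfig":
        text = resources.files("btc_cea.configs").joinpath(f"{name}.yaml").read_text()
        return cls.model_validate(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Content hash, insensitive to key order in the source file."""
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    # ------------------------------------------------------ model inputs
    def survival_specs(self) -> dict[str, dict[str, ParametricModelSpec]]:
        return {arm: {"os": s.os.spec(), "pfs": s.pfs.spec()}
                for arm, s in self.survival.items()}

    def build_inputs(self, perspective: str,
                     overrides: dict[str, float] | None = None) -> ScenarioInputs:
        """Flatten one payer perspective to plain-float model inputs.

        ``overrides`` maps dotted parameter paths (see :meth:`param_index`)
        to replacement values, used by the sensitivity analyses.
        """
        if perspective not in self.wtp or perspective not in self.costs:
            raise ValueError(f"unknown perspective {perspective!r}; "
                             f"have {sorted(self.costs)}")
        v = self._value_tree()
        for path, val in (overrides or {}).items():
            _set_path(v, path, float(val))

        utilities = UtilityInputs(
            u_pfs=v["utilities"]["pfs"],
            u_pd=v["utilities"]["pd"],
            disutilities=dict(v["disutilities"]),
            ae_duration_years=self.utilities.ae_duration_years,
        )
        costs = CostInputs(
            drugs=dict(v["costs"][perspective]["drugs"]),
            followup=dict(v["followup"]),
            ae_costs=dict(v["ae"]["costs"]),
        )
        ae = AEProfile(risks={a: dict(r) for a, r in v["ae"]["risks"].items()})
        mix = SubsequentTherapyMix(
            proportions={a: dict(p)
                         for a, p in v["subsequent_therapy"]["proportions"].items()},
            regimens={k: list(vv) for k, vv in
                      self.subsequent_therapy.regimens.items()},
            max_cycles=self.subsequent_therapy.max_cycles,
        )
        rules = TreatmentRules(
            gp_max_cycles=self.treatment.gp_max_cycles,
            durva_max_months=self.treatment.durvalumab_max_months,
        )
        return ScenarioInputs(
            settings=self.settings.to_settings(),
            utilities=utilities, costs=costs, ae=ae, mix=mix, rules=rules,
            wtp=self.wtp[perspective], perspective=perspective,
        )

    def _value_tree(self) -> dict:
        """Nested dict of plain parameter values."""
        return {
            "utilities": {"pfs": self.utilities.pfs.value,
                          "pd": self.utilities.pd.value},
            "disutilities": {k: p.value for k, p in self.disutilities.items()},
            "ae": {
                "risks": {a: {k: p.value for k, p in rr.items()}
                          for a, rr in self.ae.risks.items()},
                "costs": {k: p.value for k, p in self.ae.costs.items()},
            },
            "costs": {persp: {"drugs": {k: p.value
                                        for k, p in c.drugs.items()}}
                      for persp, c in self.costs.items()},
            "followup": {k: p.value for k, p in self.followup.items()},
            "subsequent_therapy": {
                "proportions": {a: {k: p.value for k, p in pp.items()}
                                for a, pp in
                                self.subsequent_therapy.proportions.items()},
            },
        }

    # -------------------------------------------- sensitivity parameters
    def param_index(self, perspective: str) -> list["FlatParam"]:
        """Every non-fixed parameter relevant to one perspective, flattened."""
        out: list[FlatParam] = []

        def add(path: str, p: Param):
            if p.dist == "fixed" or p.low is None or p.high is None:
                return
            out.append(FlatParam(path, p.value, p.low, p.high, p.dist))

        add("utilities.pfs", self.utilities.pfs)
        add("utilities.pd", self.utilities.pd)
        for k, p in self.disutilities.items():
            add(f"disutilities.{k}", p)
        for arm, rr in self.ae.risks.items():
            for k, p in rr.items():
                add(f"ae.risks.{arm}.{k}", p)
        for k, p in self.ae.costs.items():
            add(f"ae.costs.{k}", p)
        for k, p in self.costs[perspective].drugs.items():
            add(f"costs.{perspective}.drugs.{k}", p)
        for k, p in self.followup.items():
            add(f"followup.{k}", p)
        for arm, pp in self.subsequent_therapy.proportions.items():
            for k, p in pp.items():
                add(f"subsequent_therapy.proportions.{arm}.{k}", p)
        return out


@dataclass(frozen=True)
class FlatParam:
    path: str
    base: float
    low: float
    high: float
    dist: str


def _set_path(tree: dict, path: str, value: float) -> None:
    keys = path.split(".")
    node = tree
    for k in keys[:-1]:
        if k not in node:
            raise KeyError(f"unknown parameter path {path!r}")
        node = node[k]
    if keys[-1] not in node:
        raise KeyError(f"unknown parameter path {path!r}")
    node[keys[-1]] = value
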