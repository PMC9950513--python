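"""Costing rules, AE burden, incremental statistics, and cost linearity."""

import dataclasses

import numpy as np
import pytest

from btc_cea.economics import (
    ArmResult,
    CostInputs,
    SubsequentTherapyMix,
    UtilityInputs,
    ae_burden,
    compute_cea,
    cycle_cost,
    evaluate_arm,
)
from tests.conftest import run_base_case


class TestCycleCost:
    def test_us_durva_mid_treatment_drug_component(self, cfg):
        """Table arithmetic: durvalumab + gemcitabine + cisplatin per cycle."""
        inputs = cfg.build_inputs("us")
        assert inputs.arm_drug_cost("durva", 3) == pytest.approx(
            11_730 + 15.06 + 8.72)  # 11,753.78
        fu = inputs.costs.state_followup("pfs")
        assert cycle_cost("pfs", "durva", 3, inputs) == pytest.approx(
            11_753.78 + fu)

    def test_death_state_costs_nothing(self, cfg):
        inputs = cfg.build_inputs("us")
        assert cycle_cost("death", "durva", 5, inputs) == 0.0

    def test_chemo_drug_cost_zero_after_cap(self, cfg):
        inputs = cfg.build_inputs("us")
        assert inputs.arm_drug_cost("chemo", inputs.rules.gp_max_cycles) == 0.0
        assert inputs.arm_drug_cost("chemo", 0) == pytest.approx(15.06 + 8.72)

    def test_first_cycle_adds_initial_workup(self, cfg):
        inputs = cfg.build_inputs("us")
        delta = cycle_cost("pfs", "chemo", 0, inputs) - cycle_cost(
            "pfs", "chemo", 1, inputs)
        assert delta == pytest.approx(482.07 + 1457.11)

    def test_unknown_state_or_arm_rejected(self, cfg):
        inputs = cfg.build_inputs("us")
        with pytest.raises(ValueError):
            cycle_cost("remission", "durva", 0, inputs)
        with pytest.raises(ValueError):
            cycle_cost("pfs", "placebo", 0, inputs)


class TestAEBurden:
    def test_expected_cost_is_risk_weighted_sum(self, cfg):
        inputs = cfg.build_inputs("us")
        cost, dec = ae_burden("durva", inputs)
        expected = 0.207 * 466 + 0.192 * 354 + 0.189 * 531 + 0.08 * 1814
        assert cost == pytest.approx(expected)  # 409.909
        expected_dec = (0.207 * 0.09 + 0.192 * 0.09 + 0.189 * 0.125
                        + 0.08 * 0.20) * inputs.utilities.ae_duration_years
        assert dec == pytest.approx(expected_dec)

    def test_arms_differ_and_zero_risks_vanish(self, cfg):
        inputs = cfg.build_inputs("us")
        c_durva, _ = ae_burden("durva", inputs)
        c_chemo, _ = ae_burden("chemo", inputs)
        assert c_chemo > 0 and c_chemo != c_durva
        zeroed = dataclasses.replace(
            inputs, ae=dataclasses.replace(
                inputs.ae, risks={a: {k: 0.0 for k in r}
                                  for a, r in inputs.ae.risks.items()}))
        assert ae_burden("durva", zeroed) == (0.0, 0.0)


class TestEvaluateArm:
    def test_matches_explicit_per_cycle_summation(self, cfg, traces):
        """Independent oracle: re-accumulate the chemo arm cost cycle by
        cycle from cycle_cost plus an explicit PD-tenure recursion."""
        inputs = cfg.build_inputs("us")
        trace = traces["chemo"]
        st = inputs.settings
        df = trace.df
        sub_rate = inputs.mix.expected_cycle_cost("chemo", inputs.costs.drugs)
        total = inputs.costs.first_visit + ae_burden("chemo", inputs)[0]
        ten = np.zeros(inputs.mix.max_cycles)
        for _, row in df.iterrows():
            k = int(row.cycle)
            disc = (1 + st.discount_cost) ** (-(k + 0.5) * st.cycle_years)
            drug_fu = (inputs.arm_drug_cost("chemo", k)
                       + inputs.costs.state_followup("pfs")) * row.pfs_mid
            pd_fu = inputs.costs.state_followup("pd") * row.pd_mid
            ten_new = np.zeros_like(ten)
            ten_new[1:] = ten[:-1] * (1 - row.p_pd_death)
            ten_new[0] = row.pd_entrants
            sub = sub_rate * 0.5 * (ten.sum() + ten_new.sum())
            total += disc * (drug_fu + pd_fu + sub)
            ten = ten_new
        got = evaluate_arm("chemo", trace, inputs)
        assert got.cost == pytest.approx(total, rel=1e-9)

    def test_cost_linearity(self, cfg, traces):
        """Doubling every unit cost doubles totals and the ICER."""
        base = run_base_case(cfg, traces, "us")
        inputs = cfg.build_inputs("us")
        doubled_costs = CostInputs(
            drugs={k: 2 * v for k, v in inputs.costs.drugs.items()},
            followup={k: 2 * v for k, v in inputs.costs.followup.items()},
            ae_costs={k: 2 * v for k, v in inputs.costs.ae_costs.items()},
        )
        doubled = dataclasses.replace(inputs, costs=doubled_costs)
        arms = {a: evaluate_arm(a, traces[a], doubled) for a in traces}
        res = compute_cea(arms, doubled.wtp, "us")
        assert res.arms["chemo"].cost == pytest.approx(
            2 * base.arms["chemo"].cost, rel=1e-12)
        assert res.icer_qaly == pytest.approx(2 * base.icer_qaly, rel=1e-12)
        assert res.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-12)

    def test_unit_utilities_make_qaly_equal_ly(self, cfg, traces):
        inputs = cfg.build_inputs("us")
        neutral = dataclasses.replace(
            inputs,
            utilities=UtilityInputs(
                u_pfs=1.0, u_pd=1.0,
                disutilities={k: 0.0
                              for k in inputs.utilities.disutilities}))
        for arm in traces:
            r = evaluate_arm(arm, traces[arm], neutral)
            assert r.qaly == pytest.approx(r.ly, rel=1e-12)

    @pytest.mark.parametrize("path", [
        "costs.us.drugs.durvalumab", "followup.bed", "ae.costs.anemia",
        "costs.us.drugs.regorafenib",
    ])
    def test_total_cost_monotone_in_cost_inputs(self, cfg, traces, path):
        lo = run_base_case(cfg, traces, "us")
        hi = run_base_case(cfg, traces, "us", overrides={
            path: 1.5 * _lookup(cfg, path)})
        for arm in ("durva", "chemo"):
            assert hi.arms[arm].cost >= lo.arms[arm].cost - 1e-9


class TestCEAStatistics:
    @staticmethod
    def _mk(cost, qaly, ly=1.0, arm="x"):
        return ArmResult(arm, cost, ly, qaly, {})

    def test_icer_from_increments(self):
        res = compute_cea({"durva": self._mk(200.0, 2.0),
                           "chemo": self._mk(100.0, 1.0)}, wtp=150.0)
        assert res.icer_qaly == pytest.approx(100.0)

    def test_zero_qaly_difference_flagged(self):
        res = compute_cea({"durva": self._mk(200.0, 1.0),
                           "chemo": self._mk(100.0, 1.0)}, wtp=150.0)
        assert res.icer_qaly is None
        assert "undefined" in res.dominance

    def test_nmb_arithmetic(self):
        res = compute_cea({"durva": self._mk(217_069.25, 1.52),
                           "chemo": self._mk(0.0, 0.0)}, wtp=150_000.0)
        assert res.nmb("durva") == pytest.approx(10_930.75)

    def test_subsequent_mix_expected_cost(self, cfg):
        inputs = cfg.build_inputs("us")
        drugs = inputs.costs.drugs
        folfox = drugs["oxaliplatin"] + drugs["calcium_folinate"] + drugs["fluorouracil"]
        expected = (0.479 * folfox + 0.047 * drugs["regorafenib"]
                    + 0.047 * drugs["durvalumab"]
                    + 0.081 * (drugs["irinotecan"] + drugs["capecitabine"]))
        got = inputs.mix.expected_cycle_cost("chemo", drugs)
        assert got == pytest.approx(expected)

    def test_proportions_exceeding_one_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            SubsequentTherapyMix(proportions={"durva": {
                "chemotherapy": 0.8, "targeted": 0.3,
                "immunotherapy": 0.0, "other": 0.0}})


def _lookup(cfg, path):
    for p in cfg.param_index("us"):
        if p.path == path:
            return p.base
    raise KeyError(path)
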