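"""Base-case cost-effectiveness analysis under both payer perspectives.

Runs the bundled 3-state Markov model (21-day cycles, 10-year horizon,
costs discounted 3%/year and effects 5%/year) and prints the base-case
table: discounted totals per strategy plus incremental cost per life-year
and per QALY.  ICERs far above the willingness-to-pay thresholds
($150,000/QALY US; $38,334/QALY China) mean the combination is not
cost-effective at current durvalumab prices."""

from btc_cea import ScenarioConfig, compute_cea, evaluate_arm, make_arm_trace

cfg = ScenarioConfig.bundled()
settings = cfg.settings.to_settings()
traces = {arm: make_arm_trace(s["os"], s["pfs"], settings)
          for arm, s in cfg.survival_specs().items()}

for perspective in ("us", "china"):
    inputs = cfg.build_inputs(perspective)
    arms = {arm: evaluate_arm(arm, tr, inputs) for arm, tr in traces.items()}
    res = compute_cea(arms, inputs.wtp, perspective)
    print(f"\n=== {perspective.upper()} payer perspective "
          f"(WTP ${inputs.wtp:,.0f}/QALY) ===")
    print(res.to_table().to_string(index=False))
    print(f"incremental NMB at WTP: ${res.incremental_nmb:,.2f} "
          f"({res.dominance})")
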