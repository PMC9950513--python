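"""One-way sensitivity analysis and durvalumab price-threshold search.

Each model parameter is moved to its range bounds with everything else at
base; the tornado table ranks parameters by the ICER span they induce.
The threshold search then asks how far the durvalumab price must fall for
the US ICER to reach the willingness-to-pay targets."""

from btc_cea import ScenarioConfig, owsa, price_threshold

cfg = ScenarioConfig.bundled()

tornado = owsa(cfg, "us")
print("top 5 parameters by ICER span ($/QALY):")
for _, row in tornado.head(5).iterrows():
    print(f"  {row.parameter:<42} span {row.span:>12,.0f} "
          f"[{row.icer_low:,.0f} .. {row.icer_high:,.0f}]")

for target in (150_000.0, 100_000.0):
    red = price_threshold(target, cfg, "us")
    print(f"price reduction for ICER = ${target:,.0f}/QALY: {red:.1%}")
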