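# btc-cea

A Markov cohort cost-effectiveness model of **durvalumab + gemcitabine/
cisplatin versus gemcitabine/cisplatin** as first-line treatment for
advanced biliary tract cancer (BTC), evaluated from the US and Chinese
payer perspectives.  The package is aimed at health-economics researchers
who want a scriptable, testable implementation of the full pipeline:

1. **Survival extrapolation** — closed-form survival/hazard/density for
   six parametric families (exponential, Weibull, gamma, log-normal,
   log-logistic, Gompertz), right-censored maximum likelihood, and AIC/BIC
   model selection (`btc_cea.survival`).
2. **Kaplan–Meier IPD reconstruction** — recover pseudo individual
   patient data from digitized KM coordinates plus a numbers-at-risk
   table, in the style of Guyot's iterative algorithm (`btc_cea.km`).
3. **Synthetic trials** — generate TOPAZ-1-like arms (n = 198 / 226) with
   known ground truth, administrative censoring and emulated figure
   digitization, so every stage is testable without any download
   (`btc_cea.simulate`).
4. **Cohort model** — three health states (progression-free, progressed,
   dead), 21-day cycles over a 10-year horizon, time-dependent transition
   probabilities from the fitted OS/PFS curves, half-cycle correction,
   discounting (`btc_cea.markov`).
5. **Economics** — per-cycle drug and follow-up costs per payer
   perspective, one-time adverse-event costs and disutilities,
   subsequent-therapy mixture in the progressed state, incremental
   cost-effectiveness statistics (`btc_cea.economics`).
6. **Sensitivity analysis** — one-way (tornado), durvalumab
   price-threshold search, and probabilistic sensitivity analysis with
   cost-effectiveness acceptability curves (`btc_cea.sensitivity`).

## Model sketch

All patients start progression-free (PFS).  Per 21-day cycle *k* starting
at time *t* (months), transitions derive from the arm's parametric
curves:

    p(PFS -> PD)    = 1 - S_PFS(t + Δ) / S_PFS(t)
    p(PD  -> Death) = 1 - S_OS(t + Δ) / S_OS(t)

Discounted life-years and QALYs accumulate over half-cycle-corrected
occupancy (u_PFS = 0.76, u_PD = 0.68); costs cover first-line drugs
(gemcitabine/cisplatin up to 8 cycles, durvalumab while progression-free
up to a duration cap), routine follow-up, one-time AE management, and a
second-line therapy mixture after progression.  The headline statistic is
the incremental cost-effectiveness ratio ICER = ΔCost/ΔQALY against the
willingness-to-pay thresholds $150,000/QALY (US) and $38,334/QALY (China,
3× 2021 GDP per capita).  An alternative transition scheme that
reproduces both input curves exactly in occupancy is available as
`transition_method: match_curves`; see `docs/methods.md`.

## Worked example

```sh
python examples/03_base_case.py
```

prints (abridged):

```
=== US payer perspective (WTP $150,000/QALY) ===
strategy      cost  incr_cost   ly  incr_ly  icer_per_ly  qaly  incr_qaly  icer_per_qaly
   chemo  54776.74        NaN 1.65      NaN          NaN  1.09        NaN            NaN
   durva 226217.33  171440.59 2.30     0.66    261104.68  1.55       0.47      367017.94
incremental NMB at WTP: $-101,372.93 (trade-off)
```

Durvalumab + chemotherapy gains 0.47 QALYs over chemotherapy alone but at
an extra discounted cost of ≈$171k, i.e. ≈$367k per QALY — far above the
US threshold, so the negative net monetary benefit says the combination
is not cost-effective at list price.  `examples/04_tornado_and_threshold.py`
shows the durvalumab price dominating the tornado diagram and computes
that the price must fall by ≈66% (US WTP $150k) or ≈81% ($100k) to become
acceptable; `examples/05_psa_ceac.py` shows a 0% acceptability
probability at both national thresholds across 1,000 probabilistic draws.

The same analyses are available from the shell:

```sh
btc-cea run --perspective us --stages base,owsa,threshold,psa --out results
btc-cea threshold --wtp 150000
```

Scenario inputs (costs, utilities, AE risks, ranges, distributions,
discounting, caps) live in one YAML file; the bundled scenario is
`src/btc_cea/configs/topaz1.yaml` and any field can be swapped via
`--config my_scenario.yaml`.

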