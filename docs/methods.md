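# Methods

## Model structure

Three health states — progression-free (PFS), progressed disease (PD),
death — with all patients starting in PFS and PD absorbing into death
only.  The cycle length is 21 days (one chemotherapy cycle) and the
horizon 10 years: `floor(10 × 365.25 / 21) = 173` full cycles, the final
partial cycle discarded.  Time unit for survival models is months with
1 month = 30.4375 days; a cycle is therefore Δ = 0.6899 months.

Arm-level survival is parametric: log-logistic OS (shape 1.81, scale
13.55 months) and log-logistic PFS (2.19, 7.07) for the intervention arm;
log-logistic OS (2.22, 11.68) and gamma PFS (shape 2.76, rate 0.38/month)
for the comparator.  The log-logistic is parameterised as
S(t) = [1 + (t/scale)^shape]^-1 so its median equals the scale — chosen
because the fitted scales (13.55 / 11.68 months) then sit next to the
trial's reported median survivals (12.8 / 11.5 months), which pins down
both the convention and the time unit.

## Transition probabilities

Two derivation schemes are implemented, selected by
`settings.transition_method`:

* **`pd_exit` (base-case default).**  Exits from PFS follow the PFS curve
  (all treated as progressions) and death occurs from PD at the OS
  curve's conditional per-cycle probability:
  `p(PFS→PD) = 1 − S_PFS(t+Δ)/S_PFS(t)`,
  `p(PD→death) = 1 − S_OS(t+Δ)/S_OS(t)`, `p(PFS→death) = 0`.
  Because the death hazard applies only to the PD compartment, cohort
  survival exceeds the OS curve (discounted life expectancy 2.30 vs 1.60
  years for the intervention arm at 5%/year).  This is the scheme whose
  outputs line up with the published base case this package reproduces,
  and the structure (death reached through progression) matches the
  published state diagram of that analysis.

* **`match_curves`.**  Death from PFS uses the all-alive conditional
  death probability and `p(PD→death)` is re-solved every cycle so that
  state occupancy reproduces *both* input curves exactly:
  `pfs(t) = S_PFS(t)` and `1 − death(t) = S_OS(t)` to ≤1e-6
  (`validate_against_curves` asserts this).  This is the internally
  consistent scheme a modeller should prefer when the survival curves
  themselves are the ground truth; with it, undiscounted life-years equal
  the restricted mean survival of the OS curve to <1%.

Both schemes clip PFS to OS on the cycle grid (with a warning) if the
curves cross, guaranteeing valid probabilities.

## Discounting and half-cycle correction

Costs are discounted at 3%/year and health effects (LY, QALY) at 5%/year
under both payer perspectives — the per-quantity reading of the source
analysis's discounting statement, which is also the only reading
consistent with it printing identical LY/QALY for both countries.  Both
rates are independently configurable per scenario.  Discount factors use
cycle-midpoint compounding, `(1+r)^(−t_mid)`; recurring quantities use
trapezoid (half-cycle-corrected) occupancy; one-time quantities (first
hospitalization work-up, AE cost and disutility) are charged at model
start undiscounted.

## Costing rules

Per 21-day cycle, 2021 USD:

* **PFS**: first-line drug acquisition — gemcitabine + cisplatin for at
  most 8 cycles (the trial regimen), durvalumab (intervention arm) while
  progression-free up to 36 months; plus routine follow-up (lab, imaging,
  bed, care).  The 8-cycle and 36-month caps are configurable: neither
  duration is printed in the source tables, so the durvalumab cap was set
  within that freedom so that discounted durvalumab spend matches the
  spend implied by the published price-threshold analysis (~12.4
  discounted person-cycles).
* **cycle 0**: one-time first-hospitalization lab + imaging, plus the
  risk-weighted one-time cost of grade ≥3 adverse events.
* **PD**: PD-level follow-up plus the expected per-cycle cost of
  second-line therapy — a mixture over chemotherapy (FOLFOX), targeted
  (regorafenib), immunotherapy (durvalumab) and other (irinotecan +
  capecitabine) at the arm's uptake proportions — charged while a
  patient's PD tenure is below 6 cycles.  Tenure is tracked with a small
  tunnel vector (deaths hit all tenures proportionally), the only
  within-state memory in the model.
* **death**: zero.

Follow-up unit costs are printed once in the source and applied under
both perspectives; bed and care costs accrue in both alive states.

QALYs use u_PFS = 0.76 and u_PD = 0.68.  Adverse-event disutilities
(−0.09 leukopenia, −0.125 anemia, −0.09 neutropenia, −0.20
thrombocytopenia) enter as a one-time risk-weighted decrement assumed to
last one year (`utilities.ae_duration_years`, configurable).  The
one-year duration is the value under which the model's QALY totals match
the published ones; a 21-day duration would shrink the decrement to
~0.004 QALYs and lift both arms' QALYs by ~0.07.

## Sensitivity analysis

* **One-way (tornado)**: every parameter with a range is set to its lower
  and upper bound (the tabulated ±20% ranges) with all else at base; the
  ICER is recomputed against the fixed comparator and entries are ranked
  by span.  Survival parameters are fixed in the model and excluded.
* **Price threshold**: bisection on a multiplicative durvalumab price
  factor until |ICER − target| < $1.  The factor scales the drug price
  itself, so the second-line immunotherapy component moves with it.
* **PSA**: gamma distributions for costs, beta for probabilities,
  utilities and disutility magnitudes.  Each distribution is
  moment-matched — mean equal to the base value and central 95% interval
  equal to the tabulated range — by a 1-D root search on the shape
  (gamma) or concentration (beta); where no member of the family attains
  the requested width (means very near 0 or 1) the spread falls back to a
  range-implied SD with a warning.  Draws are seeded and bit-reproducible;
  the CEAC reports the fraction of draws with positive incremental net
  monetary benefit per WTP value.

Because the survival models are fixed, the cohort traces are computed
once and each PSA draw re-prices the same occupancy — 1,000 draws run in
a few seconds.

## Synthetic data generator

`TrialSimSpec` emulates the source trial: arm sizes 198/226, event times
drawn from the scenario survival models, uniform accrual over 12
months against a 24-month data cutoff (administrative censoring), a
60-point digitization grid over 0–24 months with Gaussian jitter
(sd 0.005) and a 6-point numbers-at-risk table.  Progression and death
draws are independent — only marginal curves are published, so no
dependence structure could be estimated — and per-subject PFS is the
minimum of the two draws, guaranteeing PFS ≤ OS.  Consequences: observed
PFS times are *not* distributed as the marginal progression model
(slightly stochastically smaller), so generator-parameter recovery is
tested on single-endpoint arms; and the generator reproduces neither
informative censoring nor digitization biases beyond point jitter, so
passing reconstruction tests demonstrate algorithmic fidelity, not
robustness to a careless digitizer.

The digitizer always includes the numbers-at-risk times among its grid
points (standard digitization practice); the reconstruction aligns
intervals on those anchors, and a coordinate exactly on a boundary
belongs to the earlier interval.

## Numerical choices

* MLE: parameters optimised in log space (meanlog free), moment-based
  start, 3-start Nelder–Mead (f-tolerance 1e-8) then BFGS polish;
  exponential uses its closed form (rate = events/Σt) exactly.
  All-censored data raise "no events"; non-convergence is flagged on the
  result, never silent.
* Model selection: minimal AIC, ties broken by BIC then by fewest
  parameters (comparisons rounded at 1e-10 to absorb float noise).
* Gompertz with non-positive shape is rejected at construction (improper
  survival distribution).
* Guyot reconstruction: within-interval censoring spread uniformly, the
  per-interval censor count iterated (≤40 rounds) to match the next
  number at risk; with a published event total, the final interval's
  censoring is chosen to match it as closely as possible.  The algorithm
  is deterministic.  KM estimation itself is delegated to lifelines.
* Monetary values are never rounded internally; tables round to 2
  decimals at the reporting layer only.

## Problem sizes

Tests use n = 5,000 samples (with ~20–30% censoring) for direct parameter
recovery, n = 226–1,000 arms for reconstruction round trips, 50
replicates of n = 2,000 for the model-selection rate, and 300–1,000 PSA
draws; the acceptance script runs 1,000 PSA draws.  These sizes hold
Monte-Carlo error comfortably inside the asserted tolerances while
keeping the full suite under a minute.

## Known limitations

* The `pd_exit` scheme intentionally lets cohort survival exceed the OS
  curve; use `match_curves` when curve fidelity matters more than
  matching the published totals.
* The 0.02 KM round-trip tolerance is meaningful only where the risk
  table keeps tens of subjects at risk; in the deep tail a single integer
  subject is itself a >2% step.
* No background (other-cause) mortality, tunnel-state utilities, dose
  individualisation (per-cycle prices are taken as printed; patient
  weight is carried but unused by the default cost path), or
  EVPI/EVPPI.
* Cost inputs are 2021 USD as printed; no CPI or currency re-adjustment.
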