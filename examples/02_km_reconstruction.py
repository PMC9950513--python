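"""Round-trip a digitized Kaplan-Meier curve back to pseudo patient data.

Simulates the control arm (n=226) of a TOPAZ-1-like trial, emulates
figure digitization (60-point grid, 0.005 jitter) plus a numbers-at-risk
table, reconstructs individual patient data, and compares the
reconstructed KM curve and a refit of the generating gamma model against
the truth.  Max deviations below ~0.02 mean the reconstruction is faithful
to the published figure."""

import numpy as np

from btc_cea import TrialSimSpec, guyot_reconstruct, km_estimate
from btc_cea.simulate import digitize, simulate_ipd
from btc_cea.survival import Family, fit_mle

arm = simulate_ipd(TrialSimSpec(seed=7))["chemo"]["pfs"]
print(f"simulated arm: n={arm.n}, events={arm.n_events}")

grid = np.linspace(0.0, 24.0, 60)
curve, risk = digitize(arm, grid, jitter_sd=0.005, seed=8)
print(f"digitized {curve.times.size} points; "
      f"numbers at risk {risk.n_risk.tolist()} at months {risk.times.tolist()}")

rec = guyot_reconstruct(curve, risk, total_events=arm.n_events)
km_true = km_estimate(arm, at_times=grid[1:])
km_rec = km_estimate(rec, at_times=grid[1:])
dev = float(np.max(np.abs(km_true.surv - km_rec.surv)))
print(f"reconstructed n={rec.n}, events={rec.n_events}; "
      f"KM round-trip max deviation {dev:.4f}")

fit = fit_mle(rec.times, rec.events, Family.GAMMA)
print("gamma refit from pseudo-IPD:",
      {k: round(v, 3) for k, v in fit.spec.named_params.items()})
print("(progression draws used gamma shape=2.76, rate=0.38; observed PFS is "
      "the minimum of the progression and death draws, so the refit sits "
      "slightly above the generator)")
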