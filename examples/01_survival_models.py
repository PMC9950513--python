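"""Fit the six candidate survival families to simulated trial data and
select by information criteria.

Simulates an uncensored sample from the durvalumab-arm overall-survival
model (log-logistic, shape 1.81, scale 13.55 months), fits all six
families, and prints the AIC/BIC ranking.  The winning family should be
the generator, and its fitted median should sit near 13.55 months."""

import numpy as np

from btc_cea import Family, ParametricModelSpec, fit_all, select_best

truth = ParametricModelSpec(Family.LOGLOGISTIC, (1.81, 13.55))
rng = np.random.default_rng(0)
times = truth.rvs(2000, rng)
events = np.ones_like(times)

fits = sorted(fit_all(times, events), key=lambda f: f.aic)
print(f"{'family':<14}{'AIC':>10}{'BIC':>10}  params")
for f in fits:
    pars = ", ".join(f"{k}={v:.3f}" for k, v in f.spec.named_params.items())
    print(f"{f.spec.family.value:<14}{f.aic:>10.1f}{f.bic:>10.1f}  {pars}")

best = select_best(fits)
print(f"\nselected: {best.spec.family.value}; "
      f"fitted median {best.spec.median():.2f} months (truth 13.55)")
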