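"""One-sample MR on a simulated cohort: 2SLS vs the naive association.

Under the default confounded-null scenario the naive logistic regression of
CKD on the smoking index finds a strong 'effect', while the instrumented
(2SLS and G-estimation) intervals include the true null — the discrepancy the
design exists to expose.
"""

import numpy as np
import pandas as pd

from smokemr import SimulationConfig, simulate_minimal
from smokemr import g_estimation_logistic, tsls_logistic, mr_power
from smokemr._regression import logistic_fit
from smokemr.instruments import first_stage_strength

config = SimulationConfig(n_individuals=20_000, seed=42)  # confounded null
d = simulate_minimal(config, seed=1)
cohort = pd.DataFrame({"ckd_event": d["y"], "smoking_index": d["x"]})
prs = d["g"] @ config.effect_vector()

f_stat, r2 = first_stage_strength(prs, d["x"])
print(f"first-stage F = {f_stat:.1f}, incremental r2 = {r2:.4f}")

naive, se, _ = logistic_fit(np.column_stack([np.ones(len(d['x'])), d["x"]]), d["y"])
print(f"naive logistic OR per index unit: {np.exp(naive[1]):.2f} "
      f"(95% CI {np.exp(naive[1]-1.96*se[1]):.2f}-{np.exp(naive[1]+1.96*se[1]):.2f})")

for est in (
    tsls_logistic(cohort, prs, covariates=[], n_boot=300, seed=2),
    g_estimation_logistic(cohort, prs, covariates=[], n_boot=300, seed=3),
):
    lo, hi = est.or_ci
    print(f"{est.method:13s} OR {est.odds_ratio:.2f} (95% CI {lo:.2f}-{hi:.2f}) "
          f"p={est.pval:.2f}")

power = mr_power(0.35, len(cohort), r2, d["y"].mean())
print(f"\npower to detect log-OR 0.35 at this instrument strength: {power:.2f}")
print("the naive interval excludes 1; the causal intervals include it —")
print("the association is driven by the planted confounder, not causation")
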