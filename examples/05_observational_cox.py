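"""Observational arm: Cox hazard ratios and the spline exposure–response.

On the confounded-null cohort the observational HR is spuriously above 1 —
compare with examples 03/04 where the causal estimators stay at the null.
"""

from smokemr import SimulationConfig, fit_cox, simulate_cohort, spline_exposure_response
from smokemr.phenotype import apply_exclusions

config = SimulationConfig(n_individuals=20_000, seed=42)
cohort, _, truth = simulate_cohort(config)
retained, _ = apply_exclusions(cohort)
print(f"retained {len(retained)} participants, "
      f"{int(retained.ckd_event.sum())} incident CKD events")
print(f"planted causal effect: {truth.true_causal_effect}")

for exposure in ("status", "index"):
    for covs in ([], ["age", "sex", "bmi", "diabetes", "hypertension"]):
        r = fit_cox(retained, exposure, covs)
        label = "adjusted" if covs else "unadjusted"
        print(f"{r.term:14s} {label:10s} HR {r.hr:.2f} "
              f"({r.ci_low:.2f}-{r.ci_high:.2f}) p={r.pval:.2g}")

curve = spline_exposure_response(retained, df_target=2)
print(f"\npenalized spline, effective df = {curve.df_effective:.2f}, "
      f"reference index = {curve.reference:.3f}")
mid = len(curve.grid) // 2
print(f"log-HR at index {curve.grid[mid]:.2f}: {curve.log_hr[mid]:+.3f} "
      f"[{curve.lower[mid]:+.3f}, {curve.upper[mid]:+.3f}]")
print("a positive, near-linear curve — entirely attributable to confounding here")
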