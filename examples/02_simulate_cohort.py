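"""Simulate a small biobank-style cohort and inspect its ground truth.

The default configuration is a confounded null: the latent confounder raises
both the smoking index and the CKD hazard while the true causal effect is 0.
"""

from smokemr import SimulationConfig, simulate_cohort
from smokemr.phenotype import apply_exclusions, baseline_table

config = SimulationConfig(n_individuals=5000, seed=7)
cohort, genotypes, truth = simulate_cohort(config)

print(f"simulated {len(cohort)} participants x {genotypes.m} SNPs")
print(f"planted causal effect: {truth.true_causal_effect} (log-odds per index unit)")
print(f"CKD events: {int(cohort.ckd_event.sum())} "
      f"({100 * cohort.ckd_event.mean():.1f}%)")
print(f"ever smokers: {100 * cohort.smoking_status.isin(['former', 'current']).mean():.1f}%")

retained, counts = apply_exclusions(cohort)
print(f"\nexclusions (first matching reason): {counts}; retained {len(retained)}")

retained = retained.assign(
    ever_smoker=(retained.smoking_status != "never").map({True: "ever", False: "never"})
)
print("\nbaseline characteristics by smoking status (counts and medians):")
print(baseline_table(retained, "ever_smoker").head(8).to_string(index=False))
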