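"""Replicate-level validation studies on the synthetic cohort.

Each study draws many cohorts under a fixed data-generating configuration and
measures a frequentist operating characteristic of the pipeline's estimators:
type-I error under the null, confidence-interval coverage at a planted
effect, robustness of the weighted median to planted invalid instruments,
calibration of the nonlinearity tests, and the headline observational-vs-MR
discrepancy rate under a confounded null.  These are the quantities the
acceptance checks assert; they are also reusable as a benchmarking surface.

All replicate seeds derive from one base seed; runtimes are kept to minutes
by the vectorized regression kernels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .instruments import InstrumentSet, compute_prs
from .mr_one_sample import g_estimation_logistic, lace_nonlinear, tsls_logistic
from .mr_two_sample import (
    harmonize,
    ivw_fixed,
    max_likelihood,
    mr_egger,
    mr_presso,
    weighted_median,
    weighted_mode,
)
from .observational import fit_cox
from .phenotype import apply_exclusions
from .simcohort import SimulationConfig, simulate_cohort, simulate_minimal, simulate_summary_stats

__all__ = [
    "calibration_rates",
    "tsls_type1_rate",
    "ivw_type1_rate",
    "pleiotropy_test_type1_rates",
    "two_sample_coverage",
    "one_sample_coverage",
    "weighted_median_breakdown",
    "lace_calibration_rates",
    "discrepancy_rate",
]


def _frame(d) -> pd.DataFrame:
    return pd.DataFrame({"ckd_event": d["y"], "smoking_index": d["x"]})


def calibration_rates(
    config: SimulationConfig, n_reps: int, seed: int = 0
) -> dict[str, float]:
    """Joint type-I-error study of the 2SLS and IVW tests under the null.

    Each replicate simulates two non-overlapping cohorts; the second provides
    both the outcome summary statistics (for IVW, paired with exposure
    statistics from the first) and the individual-level data for the 2SLS
    test, so one pass measures both rejection rates.
    """
    assert config.causal_effect == 0.0
    from ._regression import per_snp_linear, per_snp_logistic
    from .simcohort import snp_panel

    snp_ids, _, ea, oa = snp_panel(config)
    gwas_config = config.with_(n_individuals=config.gwas_n_individuals)
    tsls_rej = ivw_rej = 0
    for rep in range(n_reps):
        sim_x = simulate_minimal(gwas_config, seed + 2 * rep)
        sim_y = simulate_minimal(gwas_config, seed + 2 * rep + 1)
        bx, sx, _ = per_snp_linear(sim_x["g"], sim_x["x"])
        by, sy, _ = per_snp_logistic(sim_y["g"], sim_y["y"])
        theta = by / bx
        w = bx**2 / sy**2
        est = np.sum(w * theta) / np.sum(w)
        z = est * np.sqrt(np.sum(w))
        ivw_rej += abs(z) > 1.959964
        prs = sim_y["g"] @ config.effect_vector()
        t = tsls_logistic(_frame(sim_y), prs, covariates=[], se_method="analytic")
        tsls_rej += t.pval < 0.05
    return {"tsls": tsls_rej / n_reps, "ivw": ivw_rej / n_reps}


def tsls_type1_rate(
    config: SimulationConfig, n_reps: int, seed: int = 0
) -> float:
    """Rejection rate of the 2SLS test under the configured null (θ must be 0)."""
    assert config.causal_effect == 0.0
    rejections = 0
    for rep in range(n_reps):
        d = simulate_minimal(config, seed + rep)
        prs = d["g"] @ config.effect_vector()
        est = tsls_logistic(_frame(d), prs, covariates=[], se_method="analytic")
        rejections += est.pval < 0.05
    return rejections / n_reps


def ivw_type1_rate(
    config: SimulationConfig, n_reps: int, seed: int = 0
) -> float:
    """Rejection rate of the fixed-effect IVW test under the configured null."""
    assert config.causal_effect == 0.0
    rejections = 0
    for rep in range(n_reps):
        ex, out = simulate_summary_stats(config, seed + 2 * rep, seed + 2 * rep + 1)
        h = harmonize(ex, out)
        rejections += ivw_fixed(h).pval < 0.05
    return rejections / n_reps


def pleiotropy_test_type1_rates(
    config: SimulationConfig, n_reps: int, seed: int = 0, n_sim: int = 500
) -> tuple[float, float]:
    """(Egger-intercept, MR-PRESSO global) rejection rates under the null
    with no planted pleiotropy."""
    assert config.pleiotropy[0] == 0.0
    egger_rej = presso_rej = 0
    for rep in range(n_reps):
        ex, out = simulate_summary_stats(config, seed + 2 * rep, seed + 2 * rep + 1)
        h = harmonize(ex, out)
        _, intercept = mr_egger(h)
        egger_rej += intercept["pval"] < 0.05
        presso_rej += mr_presso(h, n_sim=n_sim, seed=seed + rep)["p_global"] < 0.05
    return egger_rej / n_reps, presso_rej / n_reps


def two_sample_coverage(
    config: SimulationConfig, theta: float, n_reps: int, seed: int = 0
) -> dict[str, float]:
    """95% CI coverage of the planted effect for IVW and maximum likelihood."""
    hits = {"ivw": 0, "maximum_likelihood": 0}
    for rep in range(n_reps):
        ex, out = simulate_summary_stats(config, seed + 2 * rep, seed + 2 * rep + 1)
        h = harmonize(ex, out)
        for est in (ivw_fixed(h), max_likelihood(h)):
            hits[est.method] += est.covers(theta)
    return {k: v / n_reps for k, v in hits.items()}


def one_sample_coverage(
    config: SimulationConfig,
    theta: float,
    n_reps: int,
    seed: int = 0,
    n_boot: int = 100,
) -> dict[str, float]:
    """95% bootstrap-CI coverage of the planted effect for 2SLS and
    G-estimation on individual-level data."""
    hits = {"2sls": 0, "g_estimation": 0}
    for rep in range(n_reps):
        d = simulate_minimal(config, seed + rep)
        prs = d["g"] @ config.effect_vector()
        frame = _frame(d)
        t = tsls_logistic(frame, prs, covariates=[], n_boot=n_boot,
                          seed=seed + 7919 + rep)
        g = g_estimation_logistic(frame, prs, covariates=[], n_boot=n_boot,
                                  seed=seed + 104729 + rep)
        hits["2sls"] += t.covers(theta)
        hits["g_estimation"] += g.covers(theta)
    return {k: v / n_reps for k, v in hits.items()}


def weighted_median_breakdown(
    config: SimulationConfig, theta: float, n_reps: int, seed: int = 0
) -> dict[str, float]:
    """Robustness contrast with planted invalid instruments.

    ``config`` should plant directional pleiotropy on a minority of SNPs.
    Returns the fraction of replicates in which the weighted median lands
    within 2 of its SEs of the planted effect, and in which IVW is biased
    away by more than 2 of its own SEs.

    The median's consistency guarantee concerns the inverse-variance *weight*
    share of valid instruments, not their count: if the invalid SNPs carry
    weight approaching one half, the weighted quantile itself shifts and the
    median degrades (as its theory predicts).  A faithful demonstration
    therefore plants pleiotropy on weaker instruments so the invalid weight
    share stays well below 0.5.
    """
    assert 0.0 < config.pleiotropy[0] < 0.5
    median_ok = ivw_biased = both = 0
    for rep in range(n_reps):
        ex, out = simulate_summary_stats(config, seed + 2 * rep, seed + 2 * rep + 1)
        h = harmonize(ex, out)
        med = weighted_median(h, n_boot=500, seed=seed + rep)
        ivw = ivw_fixed(h)
        m_ok = abs(med.beta - theta) < 2 * med.se
        i_bad = abs(ivw.beta - theta) > 2 * ivw.se
        median_ok += m_ok
        ivw_biased += i_bad
        both += m_ok and i_bad
    return {
        "median_within_2se": median_ok / n_reps,
        "ivw_biased": ivw_biased / n_reps,
        "both": both / n_reps,
    }


def lace_calibration_rates(
    config: SimulationConfig, n_reps: int, seed: int = 0
) -> tuple[float, float]:
    """Rejection rates of the two nonlinearity tests under linear truth."""
    quad = q = 0
    for rep in range(n_reps):
        d = simulate_minimal(config, seed + rep)
        prs = d["g"] @ config.effect_vector()
        res = lace_nonlinear(_frame(d), prs, covariates=[])
        quad += res.p_quadratic < 0.05
        q += res.p_q < 0.05
    return quad / n_reps, q / n_reps


_COX_COVARIATES = ["age", "sex", "bmi", "diabetes", "hypertension"]


def discrepancy_rate(
    config: SimulationConfig,
    n_reps: int,
    seed: int = 0,
    mr_boot: int = 500,
) -> dict[str, float]:
    """The central qualitative pattern under a confounded null.

    Per replicate: the covariate-adjusted Cox HR for the smoking index must
    exclude 1 while the CIs of every MR estimator — one-sample 2SLS and
    G-estimation, and the five summary-statistics estimators — include the
    null.  Returns the joint rate and the two marginal rates.
    """
    assert config.causal_effect == 0.0
    cox_hits = mr_hits = joint = 0
    for rep in range(n_reps):
        cfg = config.with_(seed=config.seed + 1000 * rep)
        cohort, geno, _ = simulate_cohort(cfg)
        retained, _ = apply_exclusions(cohort)
        cox = fit_cox(retained, "index", covariates=_COX_COVARIATES)
        cox_sig = cox.ci_low > 1.0 or cox.ci_high < 1.0

        inst = InstrumentSet(geno.snp_ids, cfg.effect_vector())
        geno_kept = geno.dosages[retained["id"].to_numpy() - 1].astype(float)
        prs = geno_kept @ inst.weights
        t = tsls_logistic(retained, prs, covariates=[], se_method="analytic")
        g = g_estimation_logistic(retained, prs, covariates=[], se_method="analytic")

        ex, out = simulate_summary_stats(cfg, seed + 2 * rep + 1, seed + 2 * rep + 2)
        h = harmonize(ex, out)
        two_sample = [
            ivw_fixed(h),
            max_likelihood(h),
            mr_egger(h)[0],
            weighted_median(h, n_boot=mr_boot, seed=seed + rep),
            weighted_mode(h, n_boot=mr_boot, seed=seed + rep + 1),
        ]
        mr_null = all(e.covers(0.0) for e in [t, g] + two_sample)
        cox_hits += cox_sig
        mr_hits += mr_null
        joint += cox_sig and mr_null
    return {
        "joint": joint / n_reps,
        "cox_excludes_null": cox_hits / n_reps,
        "all_mr_include_null": mr_hits / n_reps,
    }
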