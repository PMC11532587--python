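"""Summary-statistics (two-sample) Mendelian randomization.

Given per-SNP associations with the exposure from one GWAS and with the
outcome from a non-overlapping GWAS, harmonized to a common effect allele,
the causal effect is estimated by five methods with complementary validity
assumptions — fixed-effect inverse-variance weighting, maximum likelihood,
MR-Egger regression, the weighted median and the weighted mode — together
with Cochran's Q heterogeneity test, the MR-Egger intercept test and the
MR-PRESSO global/outlier test for horizontal pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimates import MrEstimate, PleiotropyReport

__all__ = [
    "harmonize",
    "wald_ratio",
    "ivw_fixed",
    "max_likelihood",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "mr_presso",
    "all_estimators",
]

log = logging.getLogger(__name__)

_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

Z95 = stats.norm.ppf(0.975)


def _normal_estimate(method, beta, se, n) -> MrEstimate:
    z = beta / se if se > 0 else np.inf
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se), float(p), int(n))


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align exposure and outcome summary statistics to a common effect allele.

    Inner join on SNP id; swapped outcome alleles flip the outcome beta sign
    and frequency.  Palindromic SNPs (A/T, C/G) are oriented by allele
    frequency when both frequencies fall outside the ambiguity window,
    otherwise dropped.  SNPs whose allele pairs neither match nor swap are
    dropped and logged.
    """
    lo, hi = palindromic_eaf_window
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if len(merged) == 0:
        raise ValueError("no shared SNPs between exposure and outcome tables")
    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = str(r.effect_allele_exp).upper(), str(r.other_allele_exp).upper()
        ea_y, oa_y = str(r.effect_allele_out).upper(), str(r.other_allele_out).upper()
        palindromic = (ea_x, oa_x) in _PALINDROMES
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_out, eaf_out = r.beta_out, r.eaf_out
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_out, eaf_out = -r.beta_out, 1.0 - r.eaf_out
        else:
            log.warning("dropping %s: allele pair mismatch (%s/%s vs %s/%s)",
                        r.snp, ea_x, oa_x, ea_y, oa_y)
            continue
        if palindromic:
            if lo <= r.eaf_exp <= hi or lo <= eaf_out <= hi:
                log.warning("dropping palindromic SNP %s: frequency in ambiguity window", r.snp)
                continue
            # strand flips are invisible from the allele labels; orient by
            # comparing which side of 0.5 the two frequencies fall on
            if (r.eaf_exp < 0.5) != (eaf_out < 0.5):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        rows.append(
            {
                "snp": r.snp,
                "beta_exp": float(r.beta_exp),
                "se_exp": float(r.se_exp),
                "beta_out": float(beta_out),
                "se_out": float(r.se_out),
                "eaf": float(r.eaf_exp),
                "palindromic": palindromic,
            }
        )
    h = pd.DataFrame(rows)
    if len(h) and (np.any(h["se_exp"] <= 0) or np.any(h["se_out"] <= 0)):
        raise ValueError("standard errors must be positive")
    return h


def wald_ratio(row) -> MrEstimate:
    """Single-SNP causal estimate: outcome beta over exposure beta, with the
    first-order standard error se_out/|beta_exp|."""
    beta_exp = float(row["beta_exp"])
    if beta_exp == 0.0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    est = float(row["beta_out"]) / beta_exp
    se = float(row["se_out"]) / abs(beta_exp)
    return _normal_estimate("wald_ratio", est, se, 1)


def _ratios_weights(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = h["beta_exp"].to_numpy(dtype=float)
    by = h["beta_out"].to_numpy(dtype=float)
    sy = h["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ZeroDivisionError("beta_exp = 0 row present; drop before estimation")
    return by / bx, bx**2 / sy**2


def ivw_fixed(h: pd.DataFrame) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights se_out**-2.
    """
    if len(h) == 0:
        raise ValueError("empty harmonized table")
    theta, w = _ratios_weights(h)
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return _normal_estimate("ivw", est, se, len(h))


def _ml_loglik(theta: float, bx, sx, by, sy) -> float:
    """Profile log-likelihood of the slope in the bivariate-normal model with
    per-SNP latent exposure effects (latent effects profiled out)."""
    xi = (bx / sx**2 + theta * by / sy**2) / (1.0 / sx**2 + theta**2 / sy**2)
    return float(
        -0.5 * np.sum(((bx - xi) / sx) ** 2) - 0.5 * np.sum(((by - theta * xi) / sy) ** 2)
    )


def max_likelihood(h: pd.DataFrame) -> MrEstimate:
    """Maximum-likelihood estimate of the causal slope.

    Bivariate normal measurement model per SNP with a common slope; started
    from the IVW estimate; SE from the observed information (numerical second
    derivative of the profile log-likelihood).
    """
    if len(h) == 0:
        raise ValueError("empty harmonized table")
    bx = h["beta_exp"].to_numpy(dtype=float)
    sx = h["se_exp"].to_numpy(dtype=float)
    by = h["beta_out"].to_numpy(dtype=float)
    sy = h["se_out"].to_numpy(dtype=float)
    start = ivw_fixed(h).beta
    res = optimize.minimize(
        lambda t: -_ml_loglik(float(t[0]), bx, sx, by, sy),
        x0=[start],
        method="BFGS",
    )
    if not np.isfinite(res.x[0]):
        raise RuntimeError(f"maximum-likelihood optimization failed: {res.message}")
    theta = float(res.x[0])
    eps = 1e-4 * max(1.0, abs(theta))
    d2 = (
        _ml_loglik(theta + eps, bx, sx, by, sy)
        - 2.0 * _ml_loglik(theta, bx, sx, by, sy)
        + _ml_loglik(theta - eps, bx, sx, by, sy)
    ) / eps**2
    if d2 >= 0:
        raise RuntimeError("maximum-likelihood optimum is not a maximum")
    se = float(np.sqrt(-1.0 / d2))
    return _normal_estimate("maximum_likelihood", theta, se, len(h))


def mr_egger(h: pd.DataFrame) -> tuple[MrEstimate, dict]:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    The exposure effects are oriented non-negative first (the method's
    identifying convention); the intercept estimates average directional
    pleiotropy and is tested against zero on M−2 degrees of freedom.
    """
    m = len(h)
    if m < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.sign(h["beta_exp"].to_numpy(dtype=float))
    bx = h["beta_exp"].to_numpy(dtype=float) * sign
    by = h["beta_out"].to_numpy(dtype=float) * sign
    w = h["se_out"].to_numpy(dtype=float) ** -2
    X = np.column_stack([np.ones(m), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    scale = float(np.sum(w * resid**2)) / (m - 2)
    cov = scale * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, m - 2)
    p_slope = 2.0 * stats.t.sf(abs(coef[1] / se[1]), m - 2)
    p_int = 2.0 * stats.t.sf(abs(coef[0] / se[0]), m - 2)
    slope = MrEstimate(
        "mr_egger", float(coef[1]), float(se[1]),
        float(coef[1] - tcrit * se[1]), float(coef[1] + tcrit * se[1]),
        float(p_slope), m,
    )
    intercept = {
        "intercept": float(coef[0]),
        "se": float(se[0]),
        "pval": float(p_int),
        "df": m - 2,
    }
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    ww = w[order]
    cum = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, cum, th))


def weighted_median(
    h: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of the Wald ratios (consistent when ≥50% of the weight
    comes from valid instruments); SE by parametric bootstrap from the stated
    normal errors of both summary tables."""
    if len(h) < 2:
        raise ValueError("weighted median needs at least 2 instruments")
    theta, w = _ratios_weights(h)
    if np.any(w <= 0):
        raise ValueError("nonpositive weights")
    est = _weighted_median_point(theta, w)
    se = _parametric_boot(h, _weighted_median_point, n_boot, seed)
    return _normal_estimate("weighted_median", est, se, len(h))


def _silverman_bandwidth(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    mad = stats.median_abs_deviation(theta, scale="normal")
    s = 0.9 * min(np.std(theta), mad if mad > 0 else np.inf) * len(theta) ** (-0.2)
    return phi * s


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    h = _silverman_bandwidth(theta, w, phi)
    if h <= 0 or not np.isfinite(h):
        # degenerate ratio distribution: exact (weighted) mode
        vals, idx = np.unique(theta, return_inverse=True)
        wsum = np.bincount(idx, weights=w)
        return float(vals[np.argmax(wsum)])
    lo, hi = theta.min() - 3 * h, theta.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2), axis=0
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted mode: the peak of the inverse-variance-weighted kernel density
    of the Wald ratios (consistent when the largest cluster of instruments is
    valid); normal kernel, modified-Silverman bandwidth scaled by
    ``bandwidth_factor``; SE by parametric bootstrap."""
    if len(h) < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    theta, w = _ratios_weights(h)
    if _silverman_bandwidth(theta, w, bandwidth_factor) <= 0:
        import warnings

        warnings.warn("degenerate ratios give zero bandwidth; using exact mode")
    est = _weighted_mode_point(theta, w, bandwidth_factor)
    se = _parametric_boot(
        h, lambda t, ww: _weighted_mode_point(t, ww, bandwidth_factor), n_boot, seed
    )
    return _normal_estimate("weighted_mode", est, se, len(h))


def _parametric_boot(h: pd.DataFrame, point_fn, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    bx = h["beta_exp"].to_numpy(dtype=float)
    sx = h["se_exp"].to_numpy(dtype=float)
    by = h["beta_out"].to_numpy(dtype=float)
    sy = h["se_out"].to_numpy(dtype=float)
    m = len(bx)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(m)
        bys = by + sy * rng.standard_normal(m)
        bxs[bxs == 0.0] = 1e-12
        theta = bys / bxs
        w = bxs**2 / sy**2
        ests[b] = point_fn(theta, w)
    return float(np.std(ests, ddof=1))


def cochran_q(h: pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across per-SNP Wald ratios."""
    m = len(h)
    if m < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments (df = M-1)")
    theta, w = _ratios_weights(h)
    ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - ivw) ** 2))
    df = m - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (through-origin WLS) slopes, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> dict:
    """MR-PRESSO global pleiotropy test with per-SNP outlier flags.

    The observed statistic is the weighted residual sum of squares of each
    SNP against its leave-one-out IVW slope; the null distribution is built
    by simulating outcome effects from normal(θ̂₍₋ⱼ₎·beta_exp_j, se_out_j)
    ``n_sim`` times.  Global p uses the plus-one rule; per-SNP outlier
    p-values are Bonferroni-flagged at 0.05/M.
    """
    m = len(h)
    if m < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    rng = np.random.default_rng(seed)
    bx = h["beta_exp"].to_numpy(dtype=float)
    by = h["beta_out"].to_numpy(dtype=float)
    sy = h["se_out"].to_numpy(dtype=float)
    w = sy**-2
    slopes = _loo_slopes(bx, by, w)
    res_obs = w * (by - slopes * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    by_sim = slopes[None, :] * bx[None, :] + sy[None, :] * rng.standard_normal((n_sim, m))
    sxy = (w * bx) @ by_sim.T  # total weighted cross-products per sim
    sxx = np.sum(w * bx * bx)
    slopes_sim = (sxy[:, None] - (w * bx)[None, :] * by_sim) / (sxx - w * bx * bx)[None, :]
    res_sim = w[None, :] * (by_sim - slopes_sim * bx[None, :]) ** 2
    rss_sim = res_sim.sum(axis=1)
    p_global = (1.0 + np.sum(rss_sim >= rss_obs)) / (1.0 + n_sim)
    p_snp = (1.0 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (1.0 + n_sim)
    outliers = [h["snp"].iloc[j] for j in range(m) if p_snp[j] < 0.05 / m]
    return {
        "rss_observed": rss_obs,
        "p_global": float(p_global),
        "outlier_pvals": pd.Series(p_snp, index=h["snp"].to_numpy()),
        "outlier_ids": outliers,
    }


def all_estimators(
    h: pd.DataFrame, seed: int = 0, n_boot: int = 1000, n_sim: int = 1000
) -> tuple[list[MrEstimate], PleiotropyReport]:
    """Run the five estimators and the full validity battery."""
    ests = [
        ivw_fixed(h),
        max_likelihood(h),
        mr_egger(h)[0],
        weighted_median(h, n_boot=n_boot, seed=seed),
        weighted_mode(h, n_boot=n_boot, seed=seed + 1),
    ]
    q, df, p_het = cochran_q(h)
    _, intercept = mr_egger(h)
    if len(h) >= 4:
        presso = mr_presso(h, n_sim=n_sim, seed=seed + 2)
        rss, p_glob, out = presso["rss_observed"], presso["p_global"], presso["outlier_ids"]
    else:
        rss, p_glob, out = np.nan, np.nan, []
    report = PleiotropyReport(
        q_statistic=q,
        q_df=df,
        p_heterogeneity=p_het,
        egger_intercept=intercept["intercept"],
        egger_intercept_se=intercept["se"],
        p_intercept=intercept["pval"],
        presso_rss_observed=rss,
        p_global=p_glob,
        outlier_ids=list(out),
    )
    return ests, report
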