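"""Individual-level (one-sample) Mendelian randomization.

The polygenic score is the single instrument.  The main estimator is
two-stage least squares with a logistic second stage: stage 1 regresses the
lifetime smoking index on the score plus covariates, stage 2 regresses the
binary CKD outcome on the stage-1 fitted values plus the same covariates.
Because the odds ratio is non-collapsible, a G-estimation variant of the
causal log-odds ratio (one-parameter structural mean model) is provided, and
the two agree in the rare-outcome limit.  Nonlinearity is probed with a
stratified localized-average-causal-effect (LACE) analysis, and the usual
subgroup / leave-one-out / reduced-score sensitivity analyses are included.

Confidence intervals default to a participant-level nonparametric bootstrap
(both stages refit per resample); the analytic stage-2 Wald interval is
available for large replicate studies where the bootstrap is not the
quantity under test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._regression import logistic_fit
from .estimates import LaceResult, MrEstimate
from .instruments import InstrumentSet, compute_prs
from .simcohort import GenotypeMatrix

__all__ = [
    "DEFAULT_COVARIATES",
    "build_design",
    "tsls_logistic",
    "g_estimation_logistic",
    "lace_nonlinear",
    "subgroup_mr",
    "leave_one_out",
    "sensitivity_prs",
    "mr_power",
]

#: covariates adjusted in both stages of the main model: age, sex,
#: assessment centre and the top 10 genetic principal components.
DEFAULT_COVARIATES = ["age", "sex", "center"] + [f"pc{i+1}" for i in range(10)]

_CATEGORICAL = {"center", "ethnicity", "income", "qualifications", "employment",
                "activity", "alcohol", "diet", "sleep"}

Z95 = stats.norm.ppf(0.975)


def _lsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via the normal equations (hot-path replacement for the
    SVD-based lstsq; the designs here are well conditioned)."""
    return np.linalg.solve(X.T @ X + 1e-10 * np.eye(X.shape[1]), X.T @ y)


def build_design(cohort: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Covariate design matrix (no intercept column); categorical fields are
    dummy-coded with the first level as reference."""
    if not covariates:
        return np.empty((len(cohort), 0))
    cols = []
    for c in covariates:
        if c in _CATEGORICAL or cohort[c].dtype == object:
            cols.append(pd.get_dummies(cohort[c].astype("category"), prefix=c,
                                       drop_first=True, dtype=float))
        else:
            cols.append(cohort[[c]].astype(float))
    return pd.concat(cols, axis=1).to_numpy(dtype=float)


def _check_instrument(z: np.ndarray) -> None:
    if np.std(z) < 1e-12:
        raise ValueError("instrument (PRS) is constant: degenerate instrument")


def _tsls_point(y: np.ndarray, x: np.ndarray, z: np.ndarray, w: np.ndarray,
                start=None, return_coef: bool = False):
    """2SLS point estimate and analytic stage-2 SE.  Returns (beta, se)."""
    n = len(y)
    d1 = np.column_stack([np.ones(n), w, z])
    coef1 = _lsq(d1, x)
    xhat = d1 @ coef1
    d2 = np.column_stack([np.ones(n), xhat, w])
    coef2, se2, _ = logistic_fit(d2, y, beta0=start, tol=1e-8)
    if return_coef:
        return float(coef2[1]), float(se2[1]), coef2
    return float(coef2[1]), float(se2[1])


def _bootstrap_draws(point_fn, n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ests[b] = point_fn(idx)
    return ests


def _wrap_bootstrap(method: str, beta: float, draws: np.ndarray, n: int) -> MrEstimate:
    """Percentile bootstrap interval with a robust spread estimate.

    The instrumented estimators are ratio-like and right-skewed; the
    percentile interval respects that skew, and the normalized-IQR spread is
    insensitive to the occasional extreme resample that inflates the plain
    bootstrap SD."""
    draws = draws[np.isfinite(draws)]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo, hi = min(lo, beta), max(hi, beta)
    q1, q3 = np.percentile(draws, [25, 75])
    se = float((q3 - q1) / (2.0 * stats.norm.ppf(0.75)))
    z = beta / se if se > 0 else np.inf
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(method, beta, se, float(lo), float(hi), float(p), n)


def _wrap(method: str, beta: float, se: float, n: int) -> MrEstimate:
    z = beta / se if se > 0 else np.inf
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(method, beta, se, beta - Z95 * se, beta + Z95 * se, float(p), n)


def tsls_logistic(
    cohort: pd.DataFrame,
    prs: np.ndarray,
    covariates: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    se_method: str = "bootstrap",
) -> MrEstimate:
    """Two-stage estimate of the causal log-OR of CKD per index unit.

    ``se_method="bootstrap"`` (default) refits both stages on ``n_boot``
    participant resamples; ``"analytic"`` uses the stage-2 Wald standard
    error, which ignores first-stage estimation error and is appropriate for
    large calibration studies of the test itself.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    z = np.asarray(prs, dtype=float)
    _check_instrument(z)
    y = cohort["ckd_event"].to_numpy(dtype=float)
    x = cohort["smoking_index"].to_numpy(dtype=float)
    w = build_design(cohort, covariates)
    n = len(y)
    beta, se_an, coef_full = _tsls_point(y, x, z, w, return_coef=True)
    if se_method == "analytic":
        return _wrap("2sls", beta, se_an, n)
    if se_method != "bootstrap":
        raise ValueError(f"unknown se_method {se_method!r}")
    draws = _bootstrap_draws(
        lambda idx: _tsls_point(y[idx], x[idx], z[idx], w[idx],
                                start=coef_full)[0],
        n, n_boot, seed,
    )
    return _wrap_bootstrap("2sls", beta, draws, n)


def _g_point(
    y: np.ndarray, x: np.ndarray, z: np.ndarray, w: np.ndarray,
    bracket: tuple[float, float],
    assoc_start: np.ndarray | None = None,
) -> float:
    """Solve the structural-mean-model estimating equation for the causal
    log-OR ψ: the covariate-residualized instrument must be uncorrelated with
    H(ψ) = expit(logit(p̂) − ψX), the outcome with the exposure effect removed
    on the logistic scale."""
    n = len(y)
    assoc = np.column_stack([np.ones(n), x, z, w])
    coef, _, _ = logistic_fit(assoc, y, beta0=assoc_start, tol=1e-8)
    eta = assoc @ coef
    dz = np.column_stack([np.ones(n), w])
    z_res = z - dz @ _lsq(dz, z)

    def estfun(psi: float) -> float:
        hpsi = special.expit(eta - psi * x)
        return float(np.sum(z_res * (hpsi - hpsi.mean())))

    # scan a grid for the sign change nearest zero (the estimating function
    # flattens as H saturates, so endpoint signs alone can miss the root)
    lo, hi = bracket
    grid = np.linspace(lo, hi, 33)
    vals = np.array([estfun(p) for p in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        raise RuntimeError(
            f"G-estimation not identified: no sign change on [{lo}, {hi}]"
        )
    j = sign_change[np.argmin(np.abs(grid[sign_change]))]
    return float(optimize.brentq(estfun, grid[j], grid[j + 1], xtol=1e-6))


def g_estimation_logistic(
    cohort: pd.DataFrame,
    prs: np.ndarray,
    covariates: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    bracket: tuple[float, float] = (-10.0, 10.0),
    se_method: str = "bootstrap",
) -> MrEstimate:
    """G-estimation of the causal odds ratio (noncollapsibility-robust)."""
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    z = np.asarray(prs, dtype=float)
    _check_instrument(z)
    y = cohort["ckd_event"].to_numpy(dtype=float)
    x = cohort["smoking_index"].to_numpy(dtype=float)
    w = build_design(cohort, covariates)
    n = len(y)
    psi = _g_point(y, x, z, w, bracket)
    if se_method == "analytic":
        # stacked M-estimator sandwich: U(ψ) depends on the fitted
        # association model, so the nuisance fit's variance is propagated
        # through the influence-function correction
        assoc = np.column_stack([np.ones(n), x, z, w])
        coef, _, _ = logistic_fit(assoc, y)
        eta = assoc @ coef
        dz = np.column_stack([np.ones(n), w])
        z_res = z - dz @ _lsq(dz, z)
        h = special.expit(eta - psi * x)
        u_i = z_res * (h - h.mean())
        dh = -x * h * (1.0 - h)
        du = float(np.sum(z_res * (dh - dh.mean())))
        w_h = h * (1.0 - h)
        c = assoc.T @ (z_res * w_h) - (np.sum(z_res) / n) * (assoc.T @ w_h)
        p_fit = special.expit(eta)
        score = assoc * (y - p_fit)[:, None]
        info = np.einsum("ij,i,il->jl", assoc, p_fit * (1.0 - p_fit), assoc)
        infl = u_i - score @ np.linalg.solve(info, c)
        se = float(np.sqrt(np.sum(infl**2)) / abs(du))
    elif se_method == "bootstrap":
        assoc_full = np.column_stack([np.ones(n), x, z, w])
        coef_full, _, _ = logistic_fit(assoc_full, y)

        def point(idx):
            try:
                return _g_point(y[idx], x[idx], z[idx], w[idx], bracket,
                                assoc_start=coef_full)
            except RuntimeError:
                return np.nan
        draws = _bootstrap_draws(point, n, n_boot, seed)
        if np.isfinite(draws).sum() < n_boot * 0.8:
            raise RuntimeError(
                "G-estimation bootstrap unstable (many non-identified resamples)"
            )
        return _wrap_bootstrap("g_estimation", psi, draws, n)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return _wrap("g_estimation", psi, se, n)


def _stratum_iv(y, x, z, w, label: str) -> tuple[MrEstimate, float]:
    n = len(y)
    if np.std(x) < 1e-12:
        raise ValueError(f"stratum {label}: constant exposure")
    if y.sum() == 0:
        raise ValueError(f"stratum {label}: no events")
    d1 = np.column_stack([np.ones(n), w, z])
    coef1 = _lsq(d1, x)
    b1 = float(coef1[-1])
    # stage-1 SE of the instrument coefficient
    resid1 = x - d1 @ coef1
    sigma2 = float(resid1 @ resid1) / (n - d1.shape[1])
    cov1 = sigma2 * np.linalg.inv(d1.T @ d1)
    se1 = float(np.sqrt(cov1[-1, -1]))
    d2 = np.column_stack([np.ones(n), z, w])
    coef2, se2v, _ = logistic_fit(d2, y)
    b2, se2 = float(coef2[1]), float(se2v[1])
    est = b2 / b1
    se = np.sqrt(se2**2 / b1**2 + b2**2 * se1**2 / b1**4)
    return _wrap(f"lace_{label}", est, float(se), n), float(np.mean(x))


def lace_nonlinear(
    cohort: pd.DataFrame,
    prs: np.ndarray,
    covariates: list[str] | None = None,
    n_strata: int = 3,
) -> LaceResult:
    """Stratified nonlinear MR via localized average causal effects.

    Participants are split into equal-size strata on the residual of the
    exposure regressed on the instrument and covariates (so strata are not
    defined by the exposure itself, avoiding collider bias); a per-stratum IV
    ratio is computed, and nonlinearity is tested with (a) the quadratic
    term of a fixed-effect meta-regression of stratum estimates on stratum
    exposure means and (b) Cochran's Q across strata.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    z = np.asarray(prs, dtype=float)
    _check_instrument(z)
    y = cohort["ckd_event"].to_numpy(dtype=float)
    x = cohort["smoking_index"].to_numpy(dtype=float)
    w = build_design(cohort, covariates)
    n = len(y)
    if n < 50 * n_strata:
        raise ValueError(f"need at least 50 participants per stratum ({n} total)")
    d1 = np.column_stack([np.ones(n), w, z])
    resid = x - d1 @ _lsq(d1, x)
    order = np.argsort(resid, kind="mergesort")  # stable: ties keep input order
    bounds = [round(k * n / n_strata) for k in range(n_strata + 1)]

    ests: list[MrEstimate] = []
    means: list[float] = []
    for k in range(n_strata):
        idx = order[bounds[k]:bounds[k + 1]]
        est, mean_x = _stratum_iv(y[idx], x[idx], z[idx], w[idx], str(k + 1))
        ests.append(est)
        means.append(mean_x)

    betas = np.array([e.beta for e in ests])
    ses = np.array([e.se for e in ests])
    wts = ses**-2
    mx = np.array(means)
    # quadratic meta-regression with known per-stratum variances
    X = np.column_stack([np.ones(n_strata), mx, mx**2])
    xtwx = X.T @ (wts[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (wts * betas))
    cov = np.linalg.inv(xtwx)
    z_quad = coef[2] / np.sqrt(cov[2, 2])
    p_quadratic = float(2.0 * stats.norm.sf(abs(z_quad)))
    pooled = float(np.sum(wts * betas) / np.sum(wts))
    q = float(np.sum(wts * (betas - pooled) ** 2))
    p_q = float(stats.chi2.sf(q, n_strata - 1))
    return LaceResult(ests, means, p_quadratic, p_q)


DEFAULT_SUBGROUPS = ("age", "sex", "diabetes", "hypertension", "bmi")


def subgroup_mr(
    cohort: pd.DataFrame,
    prs: np.ndarray,
    covariates: list[str] | None = None,
    subgroups: tuple[str, ...] = DEFAULT_SUBGROUPS,
    age_cut: float | None = None,
    bmi_cut: float = 25.0,
    min_n: int = 100,
    **tsls_kwargs,
) -> pd.DataFrame:
    """Two-stage estimates within subgroup levels.

    Default layout: age below/at-or-above the cohort median, sex, diabetes,
    hypertension, and BMI below/at-or-above 25 — two levels for each of the
    five variables.  Subgroup covariate lists drop the stratifying variable.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    z = np.asarray(prs, dtype=float)
    rows = []
    for var in subgroups:
        if var == "age":
            cut = float(np.median(cohort["age"])) if age_cut is None else age_cut
            levels = {f"<{cut:g}": cohort["age"] < cut, f">={cut:g}": cohort["age"] >= cut}
        elif var == "bmi":
            levels = {f"<{bmi_cut:g}": cohort["bmi"] < bmi_cut,
                      f">={bmi_cut:g}": cohort["bmi"] >= bmi_cut}
        else:
            levels = {str(v): cohort[var] == v for v in sorted(cohort[var].unique())}
        for label, mask in levels.items():
            m = mask.to_numpy()
            if m.sum() < min_n:
                warnings.warn(f"skipping subgroup {var}={label}: fewer than {min_n} rows")
                continue
            covs = [c for c in covariates if c != var]
            try:
                est = tsls_logistic(cohort.loc[m], z[m], covariates=covs, **tsls_kwargs)
            except RuntimeError as exc:
                warnings.warn(f"skipping subgroup {var}={label}: {exc}")
                continue
            rows.append({"variable": var, "level": label, **est.as_row()})
    return pd.DataFrame(rows)


def leave_one_out(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    instruments: InstrumentSet,
    covariates: list[str] | None = None,
    **tsls_kwargs,
) -> pd.DataFrame:
    """Re-estimate with each instrument SNP excluded from the score in turn."""
    if instruments.m < 2:
        raise ValueError("leave-one-out needs at least 2 instruments")
    rows = []
    for snp in instruments.snp_ids:
        reduced = instruments.without(snp)
        prs = compute_prs(genotypes, reduced)
        est = tsls_logistic(cohort, prs, covariates=covariates, **tsls_kwargs)
        rows.append({"excluded_snp": snp, **est.as_row()})
    return pd.DataFrame(rows)


def sensitivity_prs(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    instruments: InstrumentSet,
    validity_report: pd.DataFrame,
    covariates: list[str] | None = None,
    **tsls_kwargs,
) -> dict[str, MrEstimate]:
    """Sensitivity re-estimates with confounder-associated SNPs removed.

    Variant (a) rebuilds the score without flagged SNPs; variant (b)
    additionally adjusts both stages for BMI, diabetes and hypertension.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    flagged = validity_report.loc[
        ~validity_report["retained_in_sensitivity"], "snp"
    ].tolist()
    reduced = instruments.without(flagged) if flagged else instruments
    prs = compute_prs(genotypes, reduced)
    est_a = tsls_logistic(cohort, prs, covariates=covariates, **tsls_kwargs)
    est_a.method = "2sls_reduced_prs"
    est_b = tsls_logistic(
        cohort, prs, covariates=covariates + ["bmi", "diabetes", "hypertension"],
        **tsls_kwargs,
    )
    est_b.method = "2sls_reduced_prs_adjusted"
    return {"reduced_prs": est_a, "reduced_prs_adjusted": est_b}


def mr_power(
    beta_causal: float,
    n: int,
    r2: float,
    case_fraction: float,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power of the instrumented test of a binary outcome.

    power = Φ(|β|·√(n·r²·f·(1−f)) − z_{1−α/2}), where r² is the variance of
    the exposure explained by the instrument and f the case fraction.
    """
    if r2 <= 0:
        raise ValueError("instrument r2 must be positive")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = abs(beta_causal) * np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction))
    return float(stats.norm.cdf(ncp - z_alpha) + stats.norm.cdf(-ncp - z_alpha))
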