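"""Synthetic biobank-style cohort generator with known causal ground truth.

The generator emulates the statistical structure a smoking→CKD Mendelian
randomization study consumes, at desk scale:

* biallelic SNP genotypes in Hardy–Weinberg proportions;
* a continuous lifetime-smoking exposure driven by the SNPs and a latent
  confounder, truncated at zero (never smokers), and decomposed for ever
  smokers into duration / time-since-cessation / intensity fields that
  reproduce the index exactly;
* a single exponential event time for incident CKD whose log-hazard is linear
  in exposure, confounder and any planted pleiotropic SNP effects; the binary
  CKD flag is "event before administrative censoring", so the survival and
  logistic arms of the pipeline see mutually consistent data;
* baseline covariates (age, sex, centre, 10 genetic PCs, BMI, diabetes,
  hypertension and the lifestyle fields a baseline table reports), with the
  confounder loading on BMI/diabetes/hypertension;
* GWAS summary statistics from two independently simulated cohorts
  (per-SNP linear regression for the exposure, logistic for the outcome).

Every random draw flows from one integer seed through a single named
generator; identical configurations and seeds give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from ._regression import per_snp_linear, per_snp_logistic
from .phenotype import HALF_LIFE_YEARS

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "TruthLedger",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_minimal",
    "simulate_summary_stats",
    "snp_panel",
    "write_cohort",
    "read_cohort",
    "write_genotypes",
    "read_genotypes",
    "write_summary_stats",
    "read_summary_stats",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Data-generating parameters for the synthetic cohort.

    The defaults encode the benchmark's reference scenario: a *confounded
    null* — no causal effect of the smoking index on CKD, but a latent
    confounder that raises both the exposure and the hazard, which is exactly
    the regime in which observational and instrumental analyses disagree.

    Parameters
    ----------
    n_individuals, n_snps
        Cohort size and instrument panel size (42 exposure-associated SNPs).
    maf_range
        Effect-allele frequencies are drawn uniformly from this interval.
    instrument_effects
        Per-allele effect of each SNP on the exposure, in index units.  A
        scalar is broadcast to all SNPs.  The default 0.1 makes the combined
        polygenic score a strong instrument (first-stage F in the hundreds at
        the default cohort size), mirroring the strong-instrument setting the
        analysis assumes.
    causal_effect
        θ, log-odds (≈ log-hazard at the 3–4% incidence simulated here) of
        CKD per index unit.  0 in the reference scenario.
    confounder_effects
        (γ_U, δ_U): effect of the standard-normal confounder U on exposure
        (index units per SD) and on the outcome log-hazard (per SD).
    pleiotropy
        (fraction, mean, sd) of SNPs given direct outcome effects, in
        log-odds per allele.
    baseline_logit
        α₀: log-odds of CKD by end of follow-up when all effects are zero;
        default logit(0.039), the incidence of the analysis cohort.
    event_rate_scale
        Baseline hazard (events/day).  Derived from ``baseline_logit`` and
        the censoring horizon when None, so that the null-case prevalence
        equals expit(α₀) exactly.
    admin_censor_days
        Administrative censoring horizon (default 4,675 days ≈ 12.8 years).
    never_smoker_fraction
        Mass of the zero-exposure (liability-threshold) group; default 0.549.
    exposure_noise_sd
        SD of the non-genetic, non-confounder exposure noise (index units).
    current_smoker_fraction
        Among ever smokers, fraction with zero time since cessation.
    missing_smoking_fraction, prevalent_fraction, dropout_fraction
        Fractions with missing smoking fields, with a pre-baseline CKD
        diagnosis, and with early (uniform) loss to follow-up — these feed
        the exclusion rules.
    gwas_n_individuals
        Sample size of each of the two summary-statistics cohorts (the
        source GWASs are much larger than the analysis cohort; 50,000 keeps
        most of the panel genome-wide significant at desk scale).
    """

    n_individuals: int = 20_000
    n_snps: int = 42
    maf_range: tuple[float, float] = (0.10, 0.50)
    instrument_effects: float | np.ndarray = 0.1
    causal_effect: float = 0.0
    confounder_effects: tuple[float, float] = (0.4, 0.5)
    pleiotropy: tuple[float, float, float] = (0.0, 0.0, 0.0)
    baseline_logit: float = float(special.logit(0.039))
    event_rate_scale: float | None = None
    admin_censor_days: float = 4675.0
    never_smoker_fraction: float = 0.549
    exposure_noise_sd: float = 0.9
    current_smoker_fraction: float = 0.30
    missing_smoking_fraction: float = 0.02
    prevalent_fraction: float = 0.02
    dropout_fraction: float = 0.01
    gwas_n_individuals: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0 and lo <= hi):
            raise ValueError("maf_range must lie strictly inside (0, 1)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        frac = self.pleiotropy[0]
        if not 0.0 <= frac <= 1.0:
            raise ValueError("pleiotropy fraction must be in [0, 1]")
        for name in ("never_smoker_fraction", "current_smoker_fraction",
                     "missing_smoking_fraction", "prevalent_fraction",
                     "dropout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.exposure_noise_sd < 0:
            raise ValueError("exposure_noise_sd must be non-negative")
        if self.admin_censor_days <= 0:
            raise ValueError("admin_censor_days must be positive")
        if self.event_rate_scale is not None and self.event_rate_scale <= 0:
            raise ValueError("event_rate_scale must be positive")

    def effect_vector(self) -> np.ndarray:
        beta = np.asarray(self.instrument_effects, dtype=float)
        if beta.ndim == 0:
            beta = np.full(self.n_snps, float(beta))
        if beta.shape != (self.n_snps,):
            raise ValueError("instrument_effects must be scalar or length n_snps")
        return beta

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """n × M biallelic dosage matrix with allele metadata."""

    dosages: np.ndarray
    snp_ids: list[str]
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosages must be n x M matching snp_ids")
        finite = self.dosages[np.isfinite(self.dosages.astype(float))]
        if not np.all(np.isin(finite, (0, 1, 2))):
            raise ValueError("dosages must be in {0, 1, 2}")
        self.eaf = np.asarray(self.eaf, dtype=float)
        if np.any(self.eaf <= 0) or np.any(self.eaf >= 1):
            raise ValueError("eaf must lie strictly inside (0, 1)")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)


@dataclass
class TruthLedger:
    """Ground truth recorded at simulation time, for parameter-recovery checks."""

    true_causal_effect: float
    true_pleiotropic_snps: list[str]
    true_confounder: np.ndarray
    true_exposure: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snp_ids and not set(self.true_pleiotropic_snps) <= set(self.snp_ids):
            raise ValueError("pleiotropic SNP ids must be a subset of the panel")


def _draw_dosages(rng: np.random.Generator, n: int, eaf: np.ndarray) -> np.ndarray:
    """Two independent allele draws per SNP (Hardy–Weinberg by construction)."""
    e = eaf[None, :]
    return (
        (rng.random((n, len(eaf))) < e).astype(np.int8)
        + (rng.random((n, len(eaf))) < e).astype(np.int8)
    )


def snp_panel(config: SimulationConfig) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """SNP metadata (ids, eaf, effect/other alleles) derived deterministically
    from the configuration seed, shared by every cohort drawn under it."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 7])
    lo, hi = config.maf_range
    eaf = rng.uniform(lo, hi, size=config.n_snps)
    snp_ids = [f"rs{100000 + 13 * i}" for i in range(config.n_snps)]
    ea_idx = rng.integers(0, 4, size=config.n_snps)
    shift = rng.integers(1, 4, size=config.n_snps)
    effect_allele = _BASES[ea_idx]
    other_allele = _BASES[(ea_idx + shift) % 4]
    return snp_ids, eaf, effect_allele, other_allele


def simulate_genotypes(
    n: int,
    eaf: np.ndarray,
    seed: int | np.random.Generator,
    snp_ids: list[str] | None = None,
    effect_allele: np.ndarray | None = None,
    other_allele: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw Hardy–Weinberg genotypes: dosage ~ Binomial(2, eaf) per SNP."""
    eaf = np.atleast_1d(np.asarray(eaf, dtype=float))
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = _draw_dosages(rng, n, eaf)
    m = len(eaf)
    if snp_ids is None:
        snp_ids = [f"rs{100000 + 13 * i}" for i in range(m)]
    if effect_allele is None:
        effect_allele = np.array(["A"] * m)
    if other_allele is None:
        other_allele = np.array(["G"] * m)
    return GenotypeMatrix(dosages, list(snp_ids), effect_allele, other_allele, eaf)


def _latent_exposure(
    config: SimulationConfig,
    dosages: np.ndarray,
    eaf: np.ndarray,
    u: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent exposure: genetic score + confounder + noise, positioned so the
    zero-truncation mass matches the target never-smoker fraction."""
    beta = config.effect_vector()
    gamma_u = config.confounder_effects[0]
    gc = dosages - 2.0 * eaf[None, :]
    var_g = float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))
    sigma = np.sqrt(var_g + gamma_u**2 + config.exposure_noise_sd**2)
    alpha_x = sigma * stats.norm.ppf(1.0 - config.never_smoker_fraction)
    noise = rng.normal(0.0, config.exposure_noise_sd, size=dosages.shape[0])
    return alpha_x + gc @ beta + gamma_u * u + noise


def _pleiotropy_effects(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(indices of pleiotropic SNPs, per-SNP direct log-odds effects).

    Derived from the configuration seed, like the SNP panel: which SNPs are
    pleiotropic is a property of the genetic architecture, identical across
    every cohort drawn under the same configuration.
    """
    frac, mean, sd = config.pleiotropy
    m = config.n_snps
    k = int(round(frac * m))
    effects = np.zeros(m)
    if k == 0:
        return np.array([], dtype=int), effects
    rng = np.random.default_rng([int(config.seed) % (2**31), 13])
    idx = rng.choice(m, size=k, replace=False)
    effects[idx] = rng.normal(mean, sd, size=k)
    return np.sort(idx), effects


def _baseline_rate(config: SimulationConfig) -> float:
    if config.event_rate_scale is not None:
        return config.event_rate_scale
    p0 = special.expit(config.baseline_logit)
    return -np.log1p(-p0) / config.admin_censor_days


def _event_times(
    config: SimulationConfig,
    x: np.ndarray,
    u: np.ndarray,
    dosages: np.ndarray,
    pleio: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    delta_u = config.confounder_effects[1]
    log_rate = (
        np.log(_baseline_rate(config))
        + config.causal_effect * x
        + delta_u * u
        + dosages @ pleio
    )
    return rng.exponential(np.exp(-log_rate))


def simulate_minimal(
    config: SimulationConfig, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Lean draw of (genotypes, confounder, exposure, binary outcome, time).

    The workhorse for replicate-level studies (calibration, coverage): only
    the variables the estimators consume, no covariate or smoking-field
    decoration.  Returns a dict with keys ``g``, ``u``, ``x``, ``y``,
    ``time`` and ``eaf``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, eaf, _, _ = snp_panel(config)
    n = config.n_individuals
    g = _draw_dosages(rng, n, eaf).astype(np.float64)
    u = rng.normal(size=n)
    x = np.maximum(_latent_exposure(config, g, eaf, u, rng), 0.0)
    _, pleio = _pleiotropy_effects(config)
    t = _event_times(config, x, u, g, pleio, rng)
    y = (t <= config.admin_censor_days).astype(float)
    return {"g": g, "u": u, "x": x, "y": y,
            "time": np.minimum(t, config.admin_censor_days), "eaf": eaf}


def _decompose_exposure(
    x: np.ndarray,
    ever: np.ndarray,
    age: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Split each ever smoker's index into (duration, tsc, intensity).

    Intensity is lognormal (median ≈ 15 cigarettes/day) truncated to
    [1, 100]; time since cessation is 0 for current smokers, else uniform
    over [1, 0.6·(age−16)]; duration then solves the index identity in
    closed form (the duration factor is an explicit exponential, monotone
    increasing, so the solution is unique).  Indices outside the attainable
    range for the sampled (tsc, intensity, age) are clipped, and the exposure
    is updated to the attained value so the round trip is exact.
    """
    n = len(x)
    dur = np.zeros(n)
    tsc = np.zeros(n)
    cig = np.zeros(n)
    idx = np.flatnonzero(ever)
    if idx.size == 0:
        return dur, tsc, cig, x.copy(), 0
    cig_e = np.clip(rng.lognormal(np.log(15.0), 0.5, size=idx.size), 1.0, 100.0)
    current = rng.random(idx.size) < config.current_smoker_fraction
    span = age[idx] - 16.0
    tsc_e = np.where(current, 0.0, rng.uniform(1.0, np.maximum(0.6 * span, 1.0 + 1e-9)))
    hl = HALF_LIFE_YEARS
    amp = 0.5 ** (tsc_e / hl) * np.log1p(cig_e)
    dur_max = np.maximum(span - tsc_e, 0.5)
    attain_hi = amp * (1.0 - 0.5 ** (dur_max / hl))
    attain_lo = amp * (1.0 - 0.5 ** (0.5 / hl))
    x_e = x[idx]
    clipped = int(np.sum((x_e > attain_hi) | (x_e < attain_lo)))
    x_e = np.clip(x_e, attain_lo, attain_hi)
    dur_e = -hl * np.log2(1.0 - x_e / amp)
    dur[idx] = dur_e
    tsc[idx] = tsc_e
    cig[idx] = cig_e
    x_out = x.copy()
    x_out[idx] = x_e
    if clipped:
        warnings.warn(
            f"{clipped} exposure value(s) outside the attainable index range "
            "were clipped during smoking-field decomposition"
        )
    return dur, tsc, cig, x_out, clipped


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, TruthLedger]:
    """Generate a full individual-level cohort with covariates and ground truth.

    Returns the cohort table (one row per participant), the genotype matrix,
    and the truth ledger recording the planted causal effect, the pleiotropic
    SNP list, the per-individual confounder and the final (post-clipping)
    exposure used to generate outcomes.
    """
    rng = np.random.default_rng(int(config.seed) % (2**31))
    snp_ids, eaf, ea, oa = snp_panel(config)
    n = config.n_individuals
    dosages = _draw_dosages(rng, n, eaf)
    geno = GenotypeMatrix(dosages, snp_ids, ea, oa, eaf)
    g = dosages.astype(np.float64)

    u = rng.normal(size=n)
    age = rng.integers(40, 70, size=n).astype(float)
    sex = (rng.random(n) < 0.455).astype(int)  # 1 = male
    center = rng.integers(0, 10, size=n)
    pcs = rng.normal(size=(n, 10))

    lat = _latent_exposure(config, g, eaf, u, rng)
    ever = lat > 0
    x = np.maximum(lat, 0.0)
    dur, tsc, cig, x, _ = _decompose_exposure(x, ever, age, config, rng)

    idx_pleio, pleio = _pleiotropy_effects(config)
    t = _event_times(config, x, u, g, pleio, rng)
    censor = np.full(n, config.admin_censor_days)
    lost = rng.random(n) < config.dropout_fraction
    censor[lost] = rng.uniform(1.0, config.admin_censor_days, size=int(lost.sum()))
    event = (t <= censor).astype(int)
    followup = np.minimum(t, censor)

    # covariates the confounder loads on
    bmi = np.clip(27.0 + 1.5 * u + rng.normal(0.0, 3.5, size=n), 15.0, 60.0)
    diabetes = (rng.random(n) < special.expit(-3.3 + 0.6 * u)).astype(int)
    hypertension = (rng.random(n) < special.expit(-1.15 + 0.6 * u)).astype(int)

    def cat(levels, probs, miss=0.0):
        v = rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)
        if miss > 0:
            v[rng.random(n) < miss] = None
        return v

    ethnicity = cat(["white", "non-white"], [0.945, 0.055], 0.003)
    income = cat(["low", "high"], [0.225, 0.775], 0.15)
    qualifications = cat(["degree", "other"], [0.33, 0.67], 0.018)
    employment = cat(["employed", "non-employed"], [0.58, 0.42], 0.004)
    activity = cat(["moderate_vigorous", "other"], [0.66, 0.34], 0.081)
    alcohol = cat(["none", "normal", "heavy"], [0.187, 0.515, 0.298], 0.074)
    diet = cat(["good", "other"], [0.732, 0.268], 0.0)
    sleep = cat(["short", "intermediate", "long"], [0.247, 0.678, 0.075], 0.006)
    dyslipidemia = (rng.random(n) < 0.145).astype(int)
    nafld = (rng.random(n) < 0.007).astype(int)

    status = np.where(ever, np.where(tsc == 0, "current", "former"), "never").astype(object)
    missing = rng.random(n) < config.missing_smoking_fraction
    prevalent = (rng.random(n) < config.prevalent_fraction).astype(int)

    index = x.copy()
    cohort = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "center": center,
            "ethnicity": ethnicity,
            "income": income,
            "qualifications": qualifications,
            "employment": employment,
            "activity": activity,
            "bmi": bmi,
            "alcohol": alcohol,
            "diet": diet,
            "sleep": sleep,
            "diabetes": diabetes,
            "hypertension": hypertension,
            "dyslipidemia": dyslipidemia,
            "nafld": nafld,
            **{f"pc{i+1}": pcs[:, i] for i in range(10)},
            "smoking_status": status,
            "smoking_duration": dur,
            "time_since_cessation": tsc,
            "cigarettes_per_day": cig,
            "smoking_index": index,
            "prevalent_ckd": prevalent,
            "followup_days": followup,
            "ckd_event": event,
        }
    )
    cohort.loc[missing, "smoking_status"] = "missing"
    cohort.loc[missing, ["smoking_duration", "time_since_cessation",
                         "cigarettes_per_day", "smoking_index"]] = np.nan

    ledger = TruthLedger(
        true_causal_effect=config.causal_effect,
        true_pleiotropic_snps=[snp_ids[i] for i in idx_pleio],
        true_confounder=u,
        true_exposure=x,
        snp_ids=snp_ids,
    )
    return cohort, geno, ledger


def simulate_summary_stats(
    config: SimulationConfig,
    seed_exposure: int,
    seed_outcome: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP GWAS summary statistics from two non-overlapping cohorts.

    The exposure table comes from per-SNP linear regression of the smoking
    index on dosage; the outcome table from per-SNP logistic regression of
    the binary CKD flag on dosage.  Monomorphic SNPs in either simulated
    cohort are excluded from both tables with a warning.
    """
    if seed_exposure == seed_outcome:
        raise ValueError("exposure and outcome cohorts need distinct seeds")
    snp_ids, eaf, ea, oa = snp_panel(config)

    gwas_config = config.with_(n_individuals=config.gwas_n_individuals)
    sim_x = simulate_minimal(gwas_config, seed_exposure)
    sim_y = simulate_minimal(gwas_config, seed_outcome)

    poly = np.ones(config.n_snps, dtype=bool)
    for sim in (sim_x, sim_y):
        poly &= sim["g"].std(axis=0) > 0
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic simulated SNP(s)"
        )

    def table(sim, beta, se, pval):
        return pd.DataFrame(
            {
                "snp": np.asarray(snp_ids)[poly],
                "effect_allele": ea[poly],
                "other_allele": oa[poly],
                "eaf": sim["g"][:, poly].mean(axis=0) / 2.0,
                "beta": beta[poly],
                "se": se[poly],
                "pval": np.clip(pval[poly], np.finfo(float).tiny, 1.0),
            }
        )

    bx, sx, px = per_snp_linear(sim_x["g"], sim_x["x"])
    by, sy, py = per_snp_logistic(sim_y["g"], sim_y["y"])
    return table(sim_x, bx, sx, px), table(sim_y, by, sy, py)


# ---------------------------------------------------------------------------
# tab-separated I/O (the de-facto GWAS summary exchange format, plus simple
# cohort/genotype tables)

SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: {sorted(missing)}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(geno: GenotypeMatrix, path, meta_path) -> None:
    pd.DataFrame(geno.dosages, columns=geno.snp_ids).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {
            "snp": geno.snp_ids,
            "effect_allele": geno.effect_allele,
            "other_allele": geno.other_allele,
            "eaf": geno.eaf,
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_genotypes(path, meta_path) -> GenotypeMatrix:
    dosages = pd.read_csv(path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")
    return GenotypeMatrix(
        dosages.to_numpy(),
        list(dosages.columns),
        meta["effect_allele"].to_numpy(),
        meta["other_allele"].to_numpy(),
        meta["eaf"].to_numpy(),
    )
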