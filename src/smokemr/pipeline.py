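"""End-to-end pipeline: simulate → phenotype → instruments → observational →
one-sample MR → two-sample MR → comparative report.

One master seed fans out to per-stage seeds by fixed offsets, so a single
configuration line controls all randomness and a rerun with the same
configuration is byte-identical.  Every stage logs row counts in/out and the
manifest records the configuration snapshot, seeds and emitted files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._regression import per_snp_linear, per_snp_logistic
from .estimates import estimates_table
from .instruments import (
    compute_prs,
    first_stage_strength,
    select_instruments,
    validate_instruments,
)
from .mr_one_sample import (
    g_estimation_logistic,
    lace_nonlinear,
    leave_one_out,
    mr_power,
    sensitivity_prs,
    subgroup_mr,
    tsls_logistic,
)
from .mr_two_sample import all_estimators, harmonize
from .observational import ADJUSTED_COVARIATES, fit_cox, spline_exposure_response
from .phenotype import apply_exclusions, baseline_table, smoking_index_frame
from .simcohort import (
    SimulationConfig,
    read_cohort,
    read_genotypes,
    read_summary_stats,
    simulate_cohort,
    simulate_summary_stats,
    write_cohort,
    write_genotypes,
    write_summary_stats,
)

__all__ = ["PipelineConfig", "RunManifest", "Pipeline", "run_pipeline", "validate_config"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "phenotype", "instruments", "observational", "mr1", "mr2", "report")

_ANALYSIS_DEFAULTS = {
    "p_threshold": 5e-8,
    "n_measured_snps": 14,
    "n_boot": 500,
    "lace_strata": 3,
    "bmi_cut": 25.0,
    "min_followup_days": 180.0,
    "palindromic_eaf_window": [0.42, 0.58],
    "spline_df": [2, 3, 4],
}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        violations = _check_dict(raw)
        if violations:
            raise ValueError("invalid configuration: " + "; ".join(violations))
        sim_kwargs = dict(raw.get("simulation", {}))
        if "maf_range" in sim_kwargs:
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        if "confounder_effects" in sim_kwargs:
            sim_kwargs["confounder_effects"] = tuple(sim_kwargs["confounder_effects"])
        if "pleiotropy" in sim_kwargs:
            sim_kwargs["pleiotropy"] = tuple(sim_kwargs["pleiotropy"])
        analysis = dict(_ANALYSIS_DEFAULTS)
        analysis.update(raw.get("analysis", {}))
        return cls(SimulationConfig(**sim_kwargs), analysis)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def as_dict(self) -> dict:
        return {
            "simulation": dataclasses.asdict(self.simulation),
            "analysis": self.analysis,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def _check_dict(raw: dict) -> list[str]:
    violations: list[str] = []
    unknown_top = set(raw) - {"simulation", "analysis"}
    for key in sorted(unknown_top):
        violations.append(f"unknown top-level key: {key}")
    sim = raw.get("simulation", {}) or {}
    for key in sorted(set(sim) - _SIM_KEYS):
        violations.append(f"unknown simulation key: {key}")
    try:
        kwargs = {k: v for k, v in sim.items() if k in _SIM_KEYS}
        for tup in ("maf_range", "confounder_effects", "pleiotropy"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        SimulationConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        violations.append(f"simulation: {exc}")
    ana = raw.get("analysis", {}) or {}
    for key in sorted(set(ana) - set(_ANALYSIS_DEFAULTS)):
        violations.append(f"unknown analysis key: {key}")
    if "p_threshold" in ana and not (0 < ana["p_threshold"] <= 1):
        violations.append("analysis.p_threshold must lie in (0, 1]")
    if "n_boot" in ana and ana["n_boot"] < 1:
        violations.append("analysis.n_boot must be >= 1")
    if "lace_strata" in ana and ana["lace_strata"] < 2:
        violations.append("analysis.lace_strata must be >= 2")
    return violations


def validate_config(path) -> list[str]:
    """Schema and range checks; returns a list of violations (empty = valid)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _check_dict(raw)


@dataclass
class RunManifest:
    config: dict
    config_digest: str
    version: str
    seeds: dict
    row_counts: dict
    outputs: list[str]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


class Pipeline:
    """Stage-wise pipeline runner with lazy file-backed state, so individual
    stages can be re-run from a populated output directory."""

    def __init__(self, config: PipelineConfig, outdir, seed: int | None = None):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        base = config.simulation.seed if seed is None else int(seed)
        self.seeds = {
            "master": base,
            "cohort": base,
            "gwas_exposure": base + 1,
            "gwas_outcome": base + 2,
            "bootstrap": base + 3,
            "two_sample": base + 4,
        }
        if seed is not None and seed != config.simulation.seed:
            self.config = PipelineConfig(
                config.simulation.with_(seed=base), config.analysis
            )
        self._cohort = None
        self._geno = None
        self._retained = None
        self._instruments = None
        self._prs = None
        self._gwas = None
        self.row_counts: dict = {}
        self.outputs: list[str] = []
        log.info("pipeline seed=%d config=%s", base, self.config.digest())

    # -- helpers -----------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _emit(self, df: pd.DataFrame, name: str) -> None:
        df.to_csv(self._path(name), sep="\t", index=False)
        self.outputs.append(name)

    def cohort(self) -> pd.DataFrame:
        if self._cohort is None:
            self._cohort = read_cohort(self._path("cohort.tsv"))
        return self._cohort

    def genotypes(self):
        if self._geno is None:
            self._geno = read_genotypes(self._path("genotypes.tsv"), self._path("snp_meta.tsv"))
        return self._geno

    def gwas(self):
        if self._gwas is None:
            self._gwas = (
                read_summary_stats(self._path("exposure_gwas.tsv")),
                read_summary_stats(self._path("outcome_gwas.tsv")),
            )
        return self._gwas

    def retained(self) -> pd.DataFrame:
        if self._retained is None:
            self.stage_phenotype()
        return self._retained

    def prs(self):
        if self._prs is None:
            self.stage_instruments()
        return self._prs

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        cohort, geno, ledger = simulate_cohort(self.config.simulation)
        exp_gwas, out_gwas = simulate_summary_stats(
            self.config.simulation, self.seeds["gwas_exposure"], self.seeds["gwas_outcome"]
        )
        self._cohort, self._geno, self._gwas = cohort, geno, (exp_gwas, out_gwas)
        self.truth = ledger
        write_cohort(cohort, self._path("cohort.tsv"))
        write_genotypes(geno, self._path("genotypes.tsv"), self._path("snp_meta.tsv"))
        write_summary_stats(exp_gwas, self._path("exposure_gwas.tsv"))
        write_summary_stats(out_gwas, self._path("outcome_gwas.tsv"))
        self.outputs += ["cohort.tsv", "genotypes.tsv", "snp_meta.tsv",
                         "exposure_gwas.tsv", "outcome_gwas.tsv"]
        self.row_counts["simulated"] = len(cohort)
        log.info("simulate: %d participants, %d SNPs", len(cohort), geno.m)

    def stage_phenotype(self) -> None:
        cohort = self.cohort().copy()
        # recompute the index from the emitted smoking fields
        cohort["smoking_index"] = smoking_index_frame(cohort)
        retained, counts = apply_exclusions(
            cohort, min_followup=self.config.analysis["min_followup_days"]
        )
        retained = retained.reset_index(drop=True)
        retained["ever_smoker"] = np.where(
            retained["smoking_status"] == "never", "never", "ever"
        )
        self._retained = retained
        self.row_counts.update({"excluded_" + k: v for k, v in counts.items()})
        self.row_counts["retained"] = len(retained)
        self._emit(baseline_table(retained, "ever_smoker"), "baseline_table.tsv")
        log.info("phenotype: retained %d of %d", len(retained), len(cohort))

    def stage_instruments(self) -> None:
        exp_gwas, out_gwas = self.gwas()
        ana = self.config.analysis
        allowed = sorted(exp_gwas["snp"])[: ana["n_measured_snps"]]
        inst = select_instruments(exp_gwas, ana["p_threshold"], allowed_ids=allowed)
        retained = self.retained()
        geno = self.genotypes()
        geno_retained = dataclasses.replace(
            geno, dosages=geno.dosages[retained["id"].to_numpy() - 1]
        )
        prs = compute_prs(geno_retained, inst)
        self._instruments = inst
        self._geno_retained = geno_retained
        self._prs = prs
        f_stat, r2 = first_stage_strength(
            prs, retained["smoking_index"].to_numpy(),
            retained[["age", "sex"] + [f"pc{i+1}" for i in range(10)]].to_numpy(dtype=float),
        )
        self.first_stage = {"F": f_stat, "r2_incremental": r2, "m": inst.m}
        self.row_counts["instruments"] = inst.m
        log.info("instruments: M=%d, F=%.1f, incremental r2=%.4f", inst.m, f_stat, r2)

    def stage_observational(self) -> None:
        retained = self.retained()
        rows = []
        for exposure in ("status", "index"):
            for covs in ([], ADJUSTED_COVARIATES):
                rows.append(fit_cox(retained, exposure, covs).as_row())
        cox_table = pd.DataFrame(rows)
        self._emit(cox_table, "cox_table.tsv")
        self.cox_table = cox_table
        curves = []
        for dfb in self.config.analysis["spline_df"]:
            curve = spline_exposure_response(retained, df_target=float(dfb))
            frame = curve.as_frame()
            frame.insert(0, "df_target", dfb)
            curves.append(frame)
        self._emit(pd.concat(curves, ignore_index=True), "spline_curve.tsv")
        log.info("observational: %d Cox fits, %d spline variants",
                 len(rows), len(curves))

    def stage_mr1(self) -> None:
        retained = self.retained()
        prs = self.prs()
        inst = self._instruments
        geno = self._geno_retained
        ana = self.config.analysis
        n_boot = int(ana["n_boot"])
        seed = self.seeds["bootstrap"]
        main = tsls_logistic(retained, prs, n_boot=n_boot, seed=seed)
        gest = g_estimation_logistic(retained, prs, n_boot=n_boot, seed=seed + 1)
        lace = lace_nonlinear(retained, prs, n_strata=int(ana["lace_strata"]))
        subgroups = subgroup_mr(
            retained, prs, bmi_cut=float(ana["bmi_cut"]),
            n_boot=max(100, n_boot // 2), seed=seed + 2,
        )
        loo = leave_one_out(retained, geno, inst, n_boot=max(50, n_boot // 5),
                            seed=seed + 3)

        # validity screen: per-SNP associations with the measured confounders
        g = geno.dosages.astype(float)
        y = retained["ckd_event"].to_numpy(dtype=float)
        conf = {}
        bx, sx, px = per_snp_linear(g, retained["bmi"].to_numpy(dtype=float))
        conf["bmi"] = pd.DataFrame({"snp": geno.snp_ids, "beta": bx, "se": sx, "pval": px})
        for name in ("diabetes", "hypertension"):
            b, s, p = per_snp_logistic(g, retained[name].to_numpy(dtype=float))
            conf[name] = pd.DataFrame({"snp": geno.snp_ids, "beta": b, "se": s, "pval": p})
        _, _, p_out = per_snp_logistic(g[:, [geno.index_of(s) for s in inst.snp_ids]], y)
        outcome_p = pd.Series(p_out, index=inst.snp_ids)
        validity = validate_instruments(inst, conf, outcome_p)
        sens = sensitivity_prs(retained, geno, inst, validity,
                               n_boot=max(100, n_boot // 2), seed=seed + 4)

        power = mr_power(
            beta_causal=main.beta if main.beta != 0 else 0.0,
            n=len(retained),
            r2=self.first_stage["r2_incremental"],
            case_fraction=float(y.mean()),
        )
        self.mr1 = {
            "2sls": main,
            "g_estimation": gest,
            "lace": lace,
            "subgroups": subgroups,
            "leave_one_out": loo,
            "sensitivity": sens,
            "validity": validity,
            "power": power,
        }
        table = estimates_table(
            [main, gest, sens["reduced_prs"], sens["reduced_prs_adjusted"]] + lace.strata
        )
        self._emit(table, "mr1_table.tsv")
        self._emit(subgroups, "mr1_subgroups.tsv")
        self._emit(loo, "mr1_leave_one_out.tsv")
        self._emit(validity, "instrument_validity.tsv")
        log.info("one-sample MR: 2SLS OR=%.3f, G-estimation OR=%.3f, power=%.2f",
                 main.odds_ratio, gest.odds_ratio, power)

    def stage_mr2(self) -> None:
        exp_gwas, out_gwas = self.gwas()
        ana = self.config.analysis
        window = tuple(ana["palindromic_eaf_window"])
        sig = exp_gwas.loc[exp_gwas["pval"] < ana["p_threshold"]]
        if len(sig) == 0:
            raise ValueError("no genome-wide significant SNPs for two-sample MR")
        h = harmonize(sig, out_gwas, palindromic_eaf_window=window)
        ests, report = all_estimators(h, seed=self.seeds["two_sample"])
        self.mr2 = {"estimates": ests, "pleiotropy": report, "harmonized": h}
        self._emit(estimates_table(ests), "mr2_table.tsv")
        self._emit(report.as_frame(), "pleiotropy_report.tsv")
        scatter = h[["snp", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()
        for e in ests:
            scatter[f"slope_{e.method}"] = e.beta
        self._emit(scatter, "mr2_scatter.tsv")
        self.row_counts["harmonized_snps"] = len(h)
        log.info("two-sample MR: IVW OR=%.3f (p=%.3f)", ests[0].odds_ratio, ests[0].pval)

    def stage_report(self) -> None:
        cox = self.cox_table
        adj = cox.loc[(cox["term"] == "smoking_index") & (cox["model"] == "adjusted")].iloc[0]
        ci_lo = float(adj["CI95"].split("-")[0])
        obs_assoc = ci_lo > 1.0 or float(adj["CI95"].split("-")[1]) < 1.0
        mr_null = all(e.covers(0.0) for e in
                      [self.mr1["2sls"], self.mr1["g_estimation"]] + self.mr2["estimates"])
        if obs_assoc and mr_null:
            verdict = "observational association present; MR null"
        elif obs_assoc:
            verdict = "observational association present; MR concordant (non-null)"
        elif mr_null:
            verdict = "no observational association; MR null"
        else:
            verdict = "no observational association; MR non-null"
        lines = [
            "Comparative summary",
            "===================",
            f"Adjusted Cox HR per index unit: {adj['HR']} ({adj['CI95']}), p={adj['P']}",
            f"One-sample 2SLS OR: {self.mr1['2sls'].odds_ratio:.3f} "
            f"({np.exp(self.mr1['2sls'].ci_low):.2f}-{np.exp(self.mr1['2sls'].ci_high):.2f})",
            f"G-estimation OR: {self.mr1['g_estimation'].odds_ratio:.3f}",
            f"Two-sample IVW OR: {self.mr2['estimates'][0].odds_ratio:.3f}",
            f"First-stage F: {self.first_stage['F']:.1f}",
            f"Power (at the estimated effect): {self.mr1['power']:.2f}",
            f"LACE nonlinearity: p_quadratic={self.mr1['lace'].p_quadratic:.3f}, "
            f"p_Q={self.mr1['lace'].p_q:.3f}",
            f"Verdict: {verdict}",
        ]
        self.verdict = verdict
        (self._path("summary.txt")).write_text("\n".join(lines) + "\n")
        self.outputs.append("summary.txt")
        log.info("report: %s", verdict)

    def run(self, stages: tuple[str, ...] = ALL_STAGES) -> RunManifest:
        for stage in stages:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                manifest = self._manifest()
                manifest.write(self._path("manifest.json"))
                raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        self.outputs.append("manifest.json")
        manifest = self._manifest()
        manifest.write(self._path("manifest.json"))
        return manifest

    def _manifest(self) -> RunManifest:
        return RunManifest(
            config=self.config.as_dict(),
            config_digest=self.config.digest(),
            version=__version__,
            seeds=self.seeds,
            row_counts=self.row_counts,
            outputs=sorted(set(self.outputs)),
        )


def run_pipeline(
    config=None, outdir="smokemr_out", seed: int | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> RunManifest:
    """Run the full pipeline (or a stage subset) and return the manifest.

    ``config`` may be a :class:`PipelineConfig`, a dict, a YAML path, or None
    for the default confounded-null scenario.
    """
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = PipelineConfig.from_yaml(config)
    return Pipeline(cfg, outdir, seed=seed).run(stages)
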