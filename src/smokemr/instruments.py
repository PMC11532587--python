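"""Genetic-instrument construction: selection, LD clumping, polygenic score.

Instruments are SNPs associated with the exposure at genome-wide significance
(P < 5e-8), optionally restricted to a directly-genotyped subset, combined
into a single weighted polygenic risk score P_j = Σ_i g_ji β_i that serves as
one strong instrument (avoiding many-weak-instrument bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._regression import ols_fit
from .simcohort import GenotypeMatrix

__all__ = [
    "InstrumentSet",
    "select_instruments",
    "clump",
    "compute_prs",
    "first_stage_strength",
    "validate_instruments",
]

GENOME_WIDE_P = 5e-8


def read_ld_table(path) -> pd.DataFrame:
    """Pairwise LD in long format: snp_a, snp_b, r2 (tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    if {"snp_a", "snp_b", "r2"} - set(df.columns):
        raise ValueError("LD file needs columns snp_a, snp_b, r2")
    return df


def read_positions(path) -> pd.DataFrame:
    """Position sidecar: snp, chromosome, position_bp (1-based, tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    if {"snp", "chromosome", "position_bp"} - set(df.columns):
        raise ValueError("positions file needs columns snp, chromosome, position_bp")
    return df


@dataclass
class InstrumentSet:
    """Selected SNPs with exposure-effect weights (index units per allele)."""

    snp_ids: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != len(self.weights):
            raise ValueError("snp_ids and weights length mismatch")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("instrument SNP ids must be unique")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights == 0):
            raise ValueError("weights must be finite and nonzero")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def without(self, snp_ids) -> "InstrumentSet":
        drop = set(np.atleast_1d(snp_ids).tolist())
        keep = [i for i, s in enumerate(self.snp_ids) if s not in drop]
        if not keep:
            raise ValueError("removing these SNPs leaves an empty instrument set")
        return InstrumentSet(
            [self.snp_ids[i] for i in keep],
            self.weights[keep],
            {**self.provenance, "removed": sorted(drop)},
        )


def select_instruments(
    stats: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    allowed_ids: list[str] | None = None,
) -> InstrumentSet:
    """Retain SNPs below the significance threshold (and, if given, within an
    allowed-id list emulating the directly-genotyped restriction)."""
    if len(stats) == 0:
        raise ValueError("summary-statistics table is empty")
    mask = stats["pval"].to_numpy() < p_threshold
    if allowed_ids is not None:
        mask &= stats["snp"].isin(set(allowed_ids)).to_numpy()
    sel = stats.loc[mask]
    if len(sel) == 0:
        raise ValueError("no SNP passes the instrument-selection criteria")
    return InstrumentSet(
        sel["snp"].tolist(),
        sel["beta"].to_numpy(dtype=float),
        {"p_threshold": p_threshold, "allowed_ids": bool(allowed_ids), "m": int(mask.sum())},
    )


def clump(
    stats: pd.DataFrame,
    ld: pd.DataFrame,
    positions: pd.DataFrame,
    r2_max: float = 0.0001,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    ``ld`` is long-format (snp_a, snp_b, r2); ``positions`` maps snp →
    (chromosome, position_bp).  The best remaining SNP is kept; SNPs within
    ``window_kb`` on the same chromosome with r² ≥ ``r2_max`` against a kept
    SNP are dropped.  Ties at equal p-value break lexicographically on snp
    id, so the result is invariant to input row order.
    """
    pos = positions.set_index("snp")
    missing_pos = set(stats["snp"]) - set(pos.index)
    if missing_pos:
        raise ValueError(f"positions missing for SNPs: {sorted(missing_pos)}")
    r2 = {}
    for a, b, v in ld[["snp_a", "snp_b", "r2"]].itertuples(index=False):
        r2[(a, b)] = float(v)
        r2[(b, a)] = float(v)

    order = stats.sort_values(["pval", "snp"], kind="mergesort")
    kept: list[str] = []
    dropped: set[str] = set()
    for row in order.itertuples(index=False):
        snp = row.snp
        if snp in dropped:
            continue
        chrom, bp = pos.loc[snp, "chromosome"], pos.loc[snp, "position_bp"]
        ok = True
        for k in kept:
            kc, kb = pos.loc[k, "chromosome"], pos.loc[k, "position_bp"]
            if kc != chrom or abs(float(kb) - float(bp)) > window_kb * 1000.0:
                continue
            pair = r2.get((snp, k))
            if pair is None:
                raise ValueError(f"missing LD entry for in-window pair ({snp}, {k})")
            if pair >= r2_max:
                ok = False
                break
        if ok:
            kept.append(snp)
        else:
            dropped.add(snp)
    return stats.loc[stats["snp"].isin(kept)].reset_index(drop=True)


def compute_prs(genotypes: GenotypeMatrix, instruments: InstrumentSet) -> np.ndarray:
    """Weighted risk-allele count P_j = Σ_i g_ji β_i.

    Dosages are aligned to each instrument's effect allele: if the genotype
    panel codes the swapped allele pair, the dosage is flipped (2 − g).
    Missing dosages are mean-imputed at 2·eaf per SNP (logged).
    """
    missing = [s for s in instruments.snp_ids if s not in genotypes.snp_ids]
    if missing:
        raise ValueError(f"instrument SNPs absent from genotypes: {missing}")
    prs = np.zeros(genotypes.n)
    n_imputed = 0
    for snp, w in zip(instruments.snp_ids, instruments.weights):
        j = genotypes.index_of(snp)
        g = genotypes.dosages[:, j].astype(float)
        nan = ~np.isfinite(g)
        if nan.any():
            g = np.where(nan, 2.0 * genotypes.eaf[j], g)
            n_imputed += int(nan.sum())
        prs += w * g
    if n_imputed:
        warnings.warn(f"mean-imputed {n_imputed} missing dosage value(s)")
    return prs


def first_stage_strength(
    prs: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Instrument strength for the combined score.

    Linear regression of the exposure on the PRS plus covariates; returns the
    F statistic of the PRS term (the squared t, single-instrument case) and
    the incremental R² relative to the covariate-only model.
    """
    prs = np.asarray(prs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    n = len(prs)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.std(prs - base @ np.linalg.lstsq(base, prs, rcond=None)[0]) < 1e-12:
        raise ValueError("PRS is constant after covariate adjustment (degenerate instrument)")
    full = np.column_stack([base, prs])
    coef, se, resid_full = ols_fit(full, exposure)
    _, _, resid_base = ols_fit(base, exposure)
    rss_full = float(resid_full @ resid_full)
    rss_base = float(resid_base @ resid_base)
    t = coef[-1] / se[-1]
    f = float(t * t) if np.isfinite(t) else np.inf
    r2_inc = (rss_base - rss_full) / rss_base if rss_base > 0 else 1.0
    if rss_full <= 1e-12 * max(rss_base, 1.0):  # exposure fully explained
        f = np.inf
        r2_inc = 1.0
    return f, float(r2_inc)


def validate_instruments(
    instruments: InstrumentSet,
    confounder_stats: dict[str, pd.DataFrame],
    outcome_pvals: pd.Series,
    gw_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Instrument-validity screen.

    Flags each instrument SNP that is associated with any named confounder at
    genome-wide significance, and any SNP directly associated with the
    outcome at the Bonferroni level 0.05/M.  SNPs absent from a confounder
    table are treated as not associated (logged).  Returns one row per SNP
    with per-confounder flags and the retained-in-sensitivity indicator.
    """
    m = instruments.m
    bonferroni = 0.05 / m
    rows = []
    for snp in instruments.snp_ids:
        row: dict = {"snp": snp}
        conf_flag = False
        for name, table in confounder_stats.items():
            hit = table.loc[table["snp"] == snp, "pval"]
            if hit.empty:
                warnings.warn(f"{snp} absent from confounder table '{name}'; treated as null")
                row[f"conf_{name}"] = False
                continue
            flag = bool(hit.iloc[0] < gw_threshold)
            row[f"conf_{name}"] = flag
            conf_flag |= flag
        p_out = outcome_pvals.get(snp, np.nan)
        out_flag = bool(p_out < bonferroni) if np.isfinite(p_out) else False
        row["outcome_pval"] = p_out
        row["outcome_flag"] = out_flag
        row["confounder_flag"] = conf_flag
        row["retained_in_sensitivity"] = not (conf_flag or out_flag)
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["bonferroni_threshold"] = bonferroni
    return report
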