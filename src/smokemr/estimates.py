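"""Result containers shared across the estimation modules.

All causal estimates are carried on the log-odds (or log-hazard) scale with
the exponentiated ratio exposed as a property, so tables can be rendered in
the OR / HR form epidemiology journals print.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MrEstimate", "CoxResult", "LaceResult", "SplineCurve", "PleiotropyReport"]


@dataclass
class MrEstimate:
    """A causal-effect estimate on the log-odds scale.

    ``beta`` is log-OR per unit of exposure (one lifetime-smoking-index unit
    here); ``ci_low``/``ci_high`` are 95% bounds on the same scale.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_used: int

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se >= 0 and np.isfinite(self.beta):
            if not (self.ci_low <= self.beta <= self.ci_high):
                raise ValueError(
                    f"inconsistent CI for {self.method}: "
                    f"[{self.ci_low}, {self.ci_high}] vs beta={self.beta}"
                )

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def covers(self, beta0: float) -> bool:
        return self.ci_low <= beta0 <= self.ci_high

    def as_row(self) -> dict:
        lo, hi = self.or_ci
        return {
            "method": self.method,
            "OR": round(self.odds_ratio, 3),
            "CI95": f"{lo:.2f}-{hi:.2f}",
            "P": f"{self.pval:.3g}",
            "beta": self.beta,
            "se": self.se,
            "n": self.n_used,
        }


def estimates_table(estimates: list[MrEstimate]) -> pd.DataFrame:
    """Render a list of estimates as a journal-style OR (95% CI) table."""
    return pd.DataFrame([e.as_row() for e in estimates])


@dataclass
class CoxResult:
    """A proportional-hazards estimate for one exposure term."""

    term: str
    hr: float
    ci_low: float
    ci_high: float
    pval: float
    n: int
    n_events: int
    adjusted: bool

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI does not bracket the HR")

    @property
    def log_hr(self) -> float:
        return float(np.log(self.hr))

    def as_row(self) -> dict:
        return {
            "term": self.term,
            "model": "adjusted" if self.adjusted else "unadjusted",
            "HR": round(self.hr, 3),
            "CI95": f"{self.ci_low:.2f}-{self.ci_high:.2f}",
            "P": f"{self.pval:.3g}",
            "n": self.n,
            "events": self.n_events,
        }


@dataclass
class LaceResult:
    """Stratified (localized average causal effect) MR output."""

    strata: list[MrEstimate]
    stratum_means: list[float]
    p_quadratic: float
    p_q: float

    def __post_init__(self) -> None:
        means = np.asarray(self.stratum_means, dtype=float)
        if not np.all(np.diff(means) > 0):
            raise ValueError("stratum exposure means must be strictly increasing")


@dataclass
class SplineCurve:
    """Penalized-spline exposure–response curve from a Cox model.

    Log-hazard ratios relative to the reference exposure (the lower trim
    percentile), with a pointwise 95% band.
    """

    grid: np.ndarray
    log_hr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    df_effective: float
    reference: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "log_hr": self.log_hr,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class PleiotropyReport:
    """Instrument-validity battery for summary-statistics MR."""

    q_statistic: float
    q_df: int
    p_heterogeneity: float
    egger_intercept: float
    egger_intercept_se: float
    p_intercept: float
    presso_rss_observed: float = np.nan
    p_global: float = np.nan
    outlier_ids: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "cochran_q",
                    "q_df",
                    "p_heterogeneity",
                    "egger_intercept",
                    "egger_intercept_se",
                    "p_egger_intercept",
                    "presso_rss_observed",
                    "p_presso_global",
                    "presso_outliers",
                ],
                "value": [
                    self.q_statistic,
                    self.q_df,
                    self.p_heterogeneity,
                    self.egger_intercept,
                    self.egger_intercept_se,
                    self.p_intercept,
                    self.presso_rss_observed,
                    self.p_global,
                    ";".join(self.outlier_ids) if self.outlier_ids else "",
                ],
            }
        )
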