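"""Composite smoking exposure, CKD outcome derivation, and cohort curation.

The exposure is the lifetime smoking index: a continuous score combining
smoking duration, time since cessation and daily intensity with an 18-year
half-life on both time axes,

    I = (1 - 0.5**(dur/18)) * 0.5**(tsc/18) * ln(intensity + 1).

It is 0 for never smokers, increases with duration and intensity, and decays
as the quit interval lengthens, so that e.g. a heavier but shorter smoking
history can score the same as a lighter, longer one.

The outcome is incident CKD stages 3-5 ascertained from an enumerated list of
ICD-9/ICD-10 diagnosis codes.  Matching is exact on the normalized code
(dots stripped, case-folded): N18.0 qualifies, a bare N18 does not, because
the clinical definition enumerates specific stage codes.
"""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "CKD_ICD_CODES",
    "lifetime_smoking_index",
    "smoking_index_frame",
    "normalize_icd",
    "derive_ckd_outcome",
    "apply_exclusions",
    "baseline_table",
    "percent",
    "days_to_years",
]

#: Qualifying diagnosis codes for CKD stages 3-5 (normalized: no dots, upper
#: case).  ICD-10 N18.x stage codes, hypertensive renal disease with renal
#: failure (I12.0, I13.1, I13.2) and ICD-9 585.9.
CKD_ICD_CODES = frozenset(
    {"N180", "N183", "N184", "N185", "N188", "N189", "I120", "I131", "I132", "5859"}
)

HALF_LIFE_YEARS = 18.0


def lifetime_smoking_index(
    duration,
    time_since_cessation,
    intensity,
    status=None,
    half_life: float = HALF_LIFE_YEARS,
):
    """Lifetime smoking index from duration, quit interval and intensity.

    Parameters
    ----------
    duration, time_since_cessation, intensity
        Years smoked, years since quitting (0 for current smokers) and
        average cigarettes per day.  Scalars or arrays.
    status
        Optional smoking-status labels (``never``/``former``/``current``/
        ``missing``).  Never smokers score exactly 0; missing status yields a
        missing (NaN) index rather than 0.
    half_life
        Half-life in years applied to both time axes (default 18).

    Returns
    -------
    Scalar or ndarray of index values (dimensionless, >= 0).
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    dur = np.asarray(duration, dtype=float)
    tsc = np.asarray(time_since_cessation, dtype=float)
    cig = np.asarray(intensity, dtype=float)
    for name, arr in (("duration", dur), ("time_since_cessation", tsc), ("intensity", cig)):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"{name} must be non-negative")
    idx = (1.0 - 0.5 ** (dur / half_life)) * 0.5 ** (tsc / half_life) * np.log1p(cig)
    if status is not None:
        st = np.asarray(status, dtype=object)
        idx = np.where(st == "never", 0.0, idx)
        idx = np.where((st == "missing") | pd.isna(st), np.nan, idx)
    if np.ndim(idx) == 0:
        return float(idx)
    return idx


def smoking_index_frame(cohort: pd.DataFrame, half_life: float = HALF_LIFE_YEARS) -> pd.Series:
    """Index for a cohort table with the standard smoking field names."""
    return pd.Series(
        lifetime_smoking_index(
            cohort["smoking_duration"].to_numpy(),
            cohort["time_since_cessation"].to_numpy(),
            cohort["cigarettes_per_day"].to_numpy(),
            status=cohort["smoking_status"].to_numpy(),
            half_life=half_life,
        ),
        index=cohort.index,
        name="smoking_index",
    )


def normalize_icd(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def read_diagnoses(path) -> pd.DataFrame:
    """Long-format diagnosis table: columns id, code, date (ISO-8601), tab-separated."""
    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    missing = {"id", "code", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"diagnosis file lacks columns: {sorted(missing)}")
    return df


def derive_ckd_outcome(
    diagnoses: pd.DataFrame,
    baseline_date: date,
    censor_date: date,
) -> tuple[int, int, int]:
    """Classify one participant's diagnosis history.

    ``diagnoses`` holds columns ``code`` and ``date`` (ISO strings or dates)
    for a single participant.  Returns ``(prevalent, incident, event_days)``:
    prevalent if any qualifying code is dated on or before baseline; incident
    if the first qualifying code falls after baseline (event_days counts from
    baseline to that code); otherwise event_days runs to the censor date.
    Undated records are skipped with a warning.
    """
    if baseline_date > censor_date:
        raise ValueError("baseline_date must not be after censor_date")
    full_days = (censor_date - baseline_date).days
    if len(diagnoses) == 0:
        return 0, 0, full_days
    codes = diagnoses["code"].map(normalize_icd)
    dates = pd.to_datetime(diagnoses["date"], errors="coerce").dt.date
    undated = dates.isna()
    if undated.any():
        warnings.warn(f"skipping {int(undated.sum())} undated diagnosis record(s)")
    qualifying = codes.isin(CKD_ICD_CODES) & ~undated
    if not qualifying.any():
        return 0, 0, full_days
    qdates = dates[qualifying]
    first = min(qdates)
    if first <= baseline_date:
        return 1, 0, full_days
    return 0, 1, (first - baseline_date).days


def derive_ckd_outcomes(
    diagnoses: pd.DataFrame,
    baseline_date: date,
    censor_date: date,
) -> pd.DataFrame:
    """Vector version of :func:`derive_ckd_outcome` over a long table with an
    ``id`` column; returns one row per participant id present."""
    rows = []
    for pid, grp in diagnoses.groupby("id", sort=True):
        prevalent, incident, days = derive_ckd_outcome(grp, baseline_date, censor_date)
        rows.append({"id": pid, "prevalent": prevalent, "incident": incident, "event_days": days})
    return pd.DataFrame(rows)


#: exclusion reasons, applied in order; a row excludable for several reasons
#: is counted once under the first matching reason.
EXCLUSION_REASONS = ("prevalent_ckd", "short_followup", "missing_exposure")


def apply_exclusions(
    cohort: pd.DataFrame,
    min_followup: float = 180.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort exclusion rules.

    Removes participants with prevalent CKD at baseline, follow-up below
    ``min_followup`` days, or a missing smoking exposure, counting each
    excluded row once under the first matching reason.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    prevalent = (
        cohort["prevalent_ckd"].fillna(0).astype(int).to_numpy()
        if "prevalent_ckd" in cohort
        else np.zeros(len(cohort), dtype=int)
    )
    short = cohort["followup_days"].to_numpy() < min_followup
    missing = cohort["smoking_index"].isna().to_numpy() | (
        cohort["smoking_status"].astype(object) == "missing"
    ).to_numpy()

    reason = np.full(len(cohort), "", dtype=object)
    reason[np.asarray(missing)] = "missing_exposure"
    reason[short] = "short_followup"
    reason[prevalent == 1] = "prevalent_ckd"

    counts = {r: int(np.sum(reason == r)) for r in EXCLUSION_REASONS}
    retained = cohort.loc[reason == ""].copy()
    assert sum(counts.values()) + len(retained) == len(cohort)
    return retained, counts


_CONTINUOUS_FIELDS = ("age", "followup_days", "smoking_index", "bmi")


def baseline_table(
    cohort: pd.DataFrame,
    stratifier: str = "ever_smoker",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline-characteristics summary stratified by smoking status.

    Categorical fields are shown as ``n (%)`` with missingness as its own
    category; continuous fields as ``median [IQR]``.  Percentages are taken
    against the stratum total.
    """
    if categorical is None:
        categorical = [
            c
            for c in (
                "ckd_event", "sex", "ethnicity", "income", "qualifications",
                "employment", "activity", "alcohol", "diet", "sleep",
                "diabetes", "hypertension", "dyslipidemia", "nafld",
            )
            if c in cohort
        ]
    if continuous is None:
        continuous = [c for c in _CONTINUOUS_FIELDS if c in cohort]

    strata: dict[str, pd.DataFrame] = {"Total": cohort}
    for level, grp in cohort.groupby(stratifier, sort=True):
        strata[str(level)] = grp

    rows = []
    header = {"variable": "n", "category": ""}
    for name, grp in strata.items():
        header[name] = str(len(grp))
    rows.append(header)
    for var in categorical:
        values = cohort[var].astype(object).where(~cohort[var].isna(), "Missing")
        for cat in pd.unique(values):
            row = {"variable": var, "category": str(cat)}
            for name, grp in strata.items():
                v = grp[var].astype(object).where(~grp[var].isna(), "Missing")
                n = int((v == cat).sum())
                row[name] = f"{n} ({percent(n, len(grp))})" if len(grp) else "0 (0.0)"
            rows.append(row)
    for var in continuous:
        row = {"variable": var, "category": "median [IQR]"}
        for name, grp in strata.items():
            if len(grp) == 0 or grp[var].dropna().empty:
                row[name] = "NA"
            else:
                q1, med, q3 = grp[var].quantile([0.25, 0.5, 0.75])
                row[name] = f"{med:.2f} [{q1:.2f}, {q3:.2f}]"
        rows.append(row)
    return pd.DataFrame(rows)


def percent(count: int, total: int, decimals: int = 1) -> str:
    """Percentage of ``count`` in ``total``, rounded to ``decimals`` places,
    as printed in baseline tables (e.g. 15135 of 489566 -> '3.1')."""
    if total == 0:
        return "NA"
    return f"{100.0 * count / total:.{decimals}f}"


def days_to_years(days: float, decimals: int = 1) -> float:
    """Follow-up in years using the 365.25-day calendar convention."""
    return round(days / 365.25, decimals)
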