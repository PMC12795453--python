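"""Seriousness classification, age grouping and stratum summaries.

A spontaneous report is *serious* under 21 CFR 600.80 when it records any of
death, a life-threatening condition, inpatient hospitalization or its
prolongation, persistent disability, or a congenital anomaly.  The
"medically important" judgement clause requires narrative review and is
deliberately out of scope: seriousness here is a pure disjunction of the
structured outcome flags (an ER visit alone is not serious).

Age groups follow the study's bins — infants dominate pediatric vaccine
reporting, so the bins are 0-1, 2-10, 11-18, 19-54 and >=55 years, with
edges [0,2), [2,11), [11,19), [19,55), [55,inf) and a separate "unknown"
label for age-missing reports.
"""

from __future__ import annotations

import datetime as dt
import fnmatch
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._util import logger, round_half_up, round_half_up_ratio

__all__ = [
    "AGE_GROUPS",
    "AGE_GROUP_LABELS",
    "CohortSpec",
    "StratumSummary",
    "classify_serious",
    "assign_age_group",
    "extract_cohort",
    "summarize_stratum",
]

_SERIOUS_FLAGS = ("died", "life_threat", "hospitalized", "hosp_prolonged",
                  "disabled", "birth_defect")

#: (label, lower inclusive, upper exclusive) partition of [0, inf)
AGE_GROUPS: list[tuple[str, float, float]] = [
    ("0-1", 0.0, 2.0),
    ("2-10", 2.0, 11.0),
    ("11-18", 11.0, 19.0),
    ("19-54", 19.0, 55.0),
    (">=55", 55.0, math.inf),
]
AGE_GROUP_LABELS = [g[0] for g in AGE_GROUPS] + ["unknown"]


def classify_serious(report) -> bool:
    """True iff any 21 CFR 600.80 outcome flag is set on the report.

    Accepts any object exposing the six boolean flag attributes
    (``died``, ``life_threat``, ``hospitalized``, ``hosp_prolonged``,
    ``disabled``, ``birth_defect``), e.g. a ``RawDataRow`` or a DataFrame row.
    """
    return any(bool(getattr(report, flag)) for flag in _SERIOUS_FLAGS)


def assign_age_group(age_years: float | None) -> str:
    """Map an age in years to its group label; missing/negative -> "unknown"."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "unknown"
    if age_years < 0:
        return "unknown"
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_years < hi:
            return label
    return "unknown"  # unreachable for finite non-negative ages


@dataclass
class CohortSpec:
    """Which reports form the target cohort.

    ``vaccine_match`` holds shell-style patterns compared case-insensitively
    against each report's vaccine codes (names and type codes); a report
    matches when any code matches any pattern.  ``date_window`` restricts on
    receive date, inclusive on both ends.  ``comparator`` is either the
    string ``"all_other_reports"`` or a list of vaccine patterns naming the
    comparator universe.
    """

    vaccine_match: list[str]
    date_window: tuple[dt.date, dt.date] | None = None
    comparator: str | list[str] = "all_other_reports"

    def __post_init__(self) -> None:
        if not self.vaccine_match:
            raise ValueError("vaccine_match must be non-empty")
        if self.date_window is not None and self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start is after end")


def _matches(codes: Iterable[str], patterns: Sequence[str]) -> bool:
    folded = [c.casefold() for c in codes]
    return any(
        fnmatch.fnmatchcase(code, pat.casefold()) for code in folded for pat in patterns
    )


def extract_cohort(reports: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Subset the report table to the cohort the spec describes.

    ``reports`` is the frame from :func:`pvsignal.io.reports_to_frame`
    (vaccine codes ';'-joined).  Returns the matching rows; an empty result
    warns rather than raising, since an over-narrow window is a user choice.
    """
    codes = reports["vaccine_codes"].str.split(";")
    mask = codes.map(lambda cs: _matches(cs, spec.vaccine_match))
    if spec.date_window is not None:
        start, end = spec.date_window
        dates = pd.to_datetime(reports["receive_date"], errors="coerce")
        mask &= (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    out = reports[mask]
    if out.empty:
        logger.warning("extract_cohort: no reports match %s", spec.vaccine_match)
    return out


@dataclass
class StratumSummary:
    """Descriptive baseline for one stratum (one column of a Table-2 layout)."""

    label: str
    n_reports: int
    sex_counts: dict[str, int] = field(default_factory=dict)
    sex_percent: dict[str, float] = field(default_factory=dict)
    age_mean: float | None = None
    age_sd: float | None = None
    age_median: float | None = None
    age_min: float | None = None
    age_max: float | None = None
    onset_mean: float | None = None
    onset_sd: float | None = None
    onset_median: float | None = None
    onset_min: float | None = None
    onset_max: float | None = None
    onset_n_missing: int = 0
    onset_missing_percent: float = 0.0
    n_serious: int = 0
    serious_percent: float = 0.0
    sd_degenerate: bool = False  # single observation: SD undefined, reported as 0


def _describe(values: pd.Series) -> tuple[float | None, ...]:
    vals = pd.to_numeric(values, errors="coerce").dropna()
    if vals.empty:
        return (None, None, None, None, None)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return (float(vals.mean()), sd, float(vals.median()), float(vals.min()), float(vals.max()))


def summarize_stratum(reports: pd.DataFrame, label: str) -> StratumSummary:
    """Compute the baseline characteristics of one report stratum.

    Percentages use the stratum size as denominator and round half-up to one
    decimal.  An empty stratum yields an ``n=0`` summary with undefined
    statistics; a single-report stratum reports SD as 0 with
    ``sd_degenerate`` set.
    """
    n = len(reports)
    summary = StratumSummary(label=label, n_reports=n)
    if n == 0:
        return summary
    sex = reports["sex"].fillna("U")
    for code in ("F", "M", "U"):
        count = int((sex == code).sum())
        summary.sex_counts[code] = count
        summary.sex_percent[code] = round_half_up_ratio(count * 100, n, 1)
    (summary.age_mean, summary.age_sd, summary.age_median,
     summary.age_min, summary.age_max) = _describe(reports["age_years"])
    (summary.onset_mean, summary.onset_sd, summary.onset_median,
     summary.onset_min, summary.onset_max) = _describe(reports["onset_interval_days"])
    summary.onset_n_missing = int(
        pd.to_numeric(reports["onset_interval_days"], errors="coerce").isna().sum()
    )
    summary.onset_missing_percent = round_half_up_ratio(summary.onset_n_missing * 100, n, 1)
    summary.n_serious = int(reports["serious"].astype(bool).sum())
    summary.serious_percent = round_half_up_ratio(summary.n_serious * 100, n, 1)
    ages = pd.to_numeric(reports["age_years"], errors="coerce").dropna()
    if len(ages) == 1:
        summary.sd_degenerate = True
    return summary


def summarize_by_age(reports: pd.DataFrame) -> dict[str, StratumSummary]:
    """Per-age-group summaries plus an "Overall" stratum.

    The overall stratum includes age-missing reports, so per-group ``n``
    values do not sum to the overall ``n`` unless every age is known.
    """
    out: dict[str, StratumSummary] = {}
    groups = reports["age_years"].map(assign_age_group)
    for label in AGE_GROUP_LABELS:
        out[label] = summarize_stratum(reports[groups == label], label)
    out["Overall"] = summarize_stratum(reports, "Overall")
    return out


def baseline_table(reports: pd.DataFrame) -> pd.DataFrame:
    """Table-2-shaped baseline frame: one column per age group + Overall."""
    summaries = summarize_by_age(reports)
    rows: dict[str, dict[str, str]] = {}

    def fmt(x: float | None, digits: int = 2) -> str:
        return "" if x is None else f"{round_half_up(x, digits):g}"

    for label, s in summaries.items():
        col: dict[str, str] = {"N": str(s.n_reports)}
        for code, name in (("F", "Female"), ("M", "Male"), ("U", "Unknown")):
            col[f"Sex {name}"] = (
                f"{s.sex_counts.get(code, 0)} ({s.sex_percent.get(code, 0.0)}%)"
                if s.n_reports else "0"
            )
        col["Age Mean (SD)"] = f"{fmt(s.age_mean)} ({fmt(s.age_sd)})" if s.age_mean is not None else ""
        col["Age Median [Min, Max]"] = (
            f"{fmt(s.age_median)} [{fmt(s.age_min)}, {fmt(s.age_max)}]"
            if s.age_median is not None else ""
        )
        col["Numdays Mean (SD)"] = (
            f"{fmt(s.onset_mean)} ({fmt(s.onset_sd)})" if s.onset_mean is not None else ""
        )
        col["Numdays Median [Min, Max]"] = (
            f"{fmt(s.onset_median)} [{fmt(s.onset_min)}, {fmt(s.onset_max)}]"
            if s.onset_median is not None else ""
        )
        col["Numdays Missing"] = f"{s.onset_n_missing} ({s.onset_missing_percent}%)"
        col["Serious Yes"] = f"{s.n_serious} ({s.serious_percent}%)"
        col["Serious No"] = (
            f"{s.n_reports - s.n_serious} "
            f"({round_half_up_ratio((s.n_reports - s.n_serious) * 100, s.n_reports, 1)}%)"
            if s.n_reports else "0"
        )
        rows[label] = col
    return pd.DataFrame(rows)
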