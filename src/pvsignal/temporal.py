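"""Time-to-onset (TTO) summaries, interval histograms and cumulative curves.

Onset is the number of days from vaccination to symptom onset (``NUMDAYS``,
with a date-difference fallback applied at assembly).  Spontaneous-report
onsets concentrate at 0-1 days with a long tail, so the mean typically far
exceeds the median; both are reported, alongside linear-interpolation
quartiles, and missing onsets are counted but never imputed.

Histograms use the fixed integer-day intervals 0-30, 31-90, 91-180,
181-360 and >360, closed on both ends (day 30 falls in the first bin,
day 31 in the second).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
import pandas as pd

from ._util import logger
from .disproportionality import normalized_frequency

__all__ = [
    "ONSET_BINS",
    "OnsetSummary",
    "OnsetHistogram",
    "onset_summary",
    "summarize_onsets",
    "onset_histogram",
    "cumulative_curve",
]

#: (label, first day, last day inclusive); None = unbounded
ONSET_BINS: list[tuple[str, int, int | None]] = [
    ("0-30", 0, 30),
    ("31-90", 31, 90),
    ("91-180", 91, 180),
    ("181-360", 181, 360),
    (">360", 361, None),
]


@dataclass(frozen=True)
class OnsetSummary:
    """TTO statistics for one PT in one stratum; NaNs when n = 0."""

    preferred_term: str
    stratum: str
    n: int
    n_missing: int
    mean: float
    median: float
    q1: float
    q3: float

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass(frozen=True)
class OnsetHistogram:
    """Binned onset counts with per-100k frequencies for one vaccine."""

    vaccine: str
    labels: tuple[str, ...]
    counts: tuple[int, ...]
    frequencies_per_100k: tuple[int, ...]
    n: int  # non-missing, non-negative onsets binned


def summarize_onsets(values: Sequence[float], pt: str = "", stratum: str = "",
                     n_missing: int = 0) -> OnsetSummary:
    """Summary statistics of a vector of onset days.

    Quartiles use linear interpolation between order statistics (the same
    convention as numpy's default quantile method).  An empty vector yields
    an all-NaN summary flagged via ``defined``.
    """
    arr = np.asarray([v for v in values if v is not None and not math.isnan(v)], dtype=float)
    if arr.size == 0:
        nan = math.nan
        return OnsetSummary(pt, stratum, 0, n_missing, nan, nan, nan, nan)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return OnsetSummary(
        preferred_term=pt,
        stratum=stratum,
        n=int(arr.size),
        n_missing=n_missing,
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def onset_summary(
    reports: pd.DataFrame,
    long_table: pd.DataFrame,
    pt: str,
    stratum_ids: Collection[str],
    stratum: str = "",
) -> OnsetSummary:
    """TTO summary for one PT restricted to the reports in ``stratum_ids``."""
    ids = set(stratum_ids) & set(
        long_table.loc[long_table["preferred_term"] == pt, "report_id"]
    )
    sub = reports[reports["report_id"].isin(ids)]
    onsets = pd.to_numeric(sub["onset_interval_days"], errors="coerce")
    n_missing = int(onsets.isna().sum())
    return summarize_onsets(onsets.dropna().tolist(), pt=pt, stratum=stratum,
                            n_missing=n_missing)


def onset_histogram(
    onsets: Sequence[float],
    vaccine_total: int,
    vaccine: str = "",
) -> OnsetHistogram:
    """Bin non-missing onsets into the fixed day intervals.

    Frequencies are per 100,000 reports of the vaccine (``vaccine_total``),
    so histograms from databases of different sizes are comparable.
    Negative onsets (data errors) are excluded with a warning.
    """
    clean = [v for v in onsets if v is not None and not math.isnan(v)]
    n_neg = sum(1 for v in clean if v < 0)
    if n_neg:
        logger.warning("onset_histogram: excluded %d negative onset(s)", n_neg)
    clean = [v for v in clean if v >= 0]
    counts = []
    for _, lo, hi in ONSET_BINS:
        if hi is None:
            counts.append(sum(1 for v in clean if v >= lo))
        else:
            counts.append(sum(1 for v in clean if lo <= v <= hi))
    freqs = tuple(normalized_frequency(c, vaccine_total) for c in counts)
    return OnsetHistogram(
        vaccine=vaccine,
        labels=tuple(label for label, _, _ in ONSET_BINS),
        counts=tuple(counts),
        frequencies_per_100k=freqs,
        n=len(clean),
    )


def cumulative_curve(onsets: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical cumulative fraction of non-missing onsets at each observed day.

    Returns (day, fraction of onsets <= day) pairs at the unique onset
    values, a nondecreasing step function reaching 1.0 at the maximum onset.
    """
    arr = np.sort(np.asarray(
        [v for v in onsets if v is not None and not math.isnan(v)], dtype=float
    ))
    if arr.size == 0:
        raise ValueError("cumulative_curve requires at least one non-missing onset")
    days, last_idx = np.unique(arr, return_index=True)
    # count of values <= day: position after the last occurrence of each unique day
    counts = np.searchsorted(arr, days, side="right")
    n = arr.size
    return [(float(day), float(cnt) / n) for day, cnt in zip(days, counts)]


def tto_table(
    reports: pd.DataFrame,
    long_table: pd.DataFrame,
    strata: dict[str, Collection[str]],
    top_k: int = 10,
) -> pd.DataFrame:
    """Table-6-shaped TTO frame: top-k PTs per stratum by report count."""
    rows = []
    for stratum, ids in strata.items():
        ids = set(ids)
        sub = long_table[long_table["report_id"].isin(ids)]
        top = (
            sub.groupby("preferred_term")["report_id"].nunique()
            .sort_values(ascending=False, kind="stable")
        )
        top = top.iloc[
            np.lexsort((top.index.astype(str), -top.to_numpy(dtype=float)))
        ][:top_k]
        for pt in top.index:
            s = onset_summary(reports, long_table, pt, ids, stratum)
            rows.append(
                {
                    "Group": stratum,
                    "PT": pt,
                    "n": s.n,
                    "n_missing": s.n_missing,
                    "median": s.median,
                    "Q1": s.q1,
                    "Q3": s.q3,
                    "mean": s.mean,
                }
            )
    return pd.DataFrame(rows, columns=["Group", "PT", "n", "n_missing",
                                       "median", "Q1", "Q3", "mean"])
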