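"""Reporting Odds Ratio (ROR) disproportionality analysis.

For each Preferred Term the target cohort is compared against a comparator
universe through a 2x2 table of *report* counts (a PT repeated within one
report counts once):

====================  ==================  =====================
                      reports with PT     reports without PT
target vaccine        a                   b
comparator            c                   d
====================  ==================  =====================

The reporting odds ratio is ``ROR = ad / bc`` with Wald standard error on
the log scale ``SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)`` and

    95% CI = exp(ln ROR ± 1.96 · SE(ln ROR)).

A PT is flagged as a signal when the lower CI bound exceeds 1.  ROR is a
measure of reporting disproportion in a spontaneous-report database, not of
incidence or causation: there is no population denominator and no
unvaccinated comparison group.

Per-100,000 normalized frequencies put counts from databases of very
different sizes on one scale:

    frequency = round_half_up(a / n_total * 100,000)

where ``n_total`` is the report total of the cohort or stratum the count
was taken in.  No multiple-testing adjustment is applied to the per-PT CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Sequence

import pandas as pd

from ._util import logger, round_half_up_ratio

__all__ = [
    "Z_95",
    "ContingencyTable",
    "RorEstimate",
    "SignalResult",
    "build_contingency",
    "compute_ror",
    "normalized_frequency",
    "screen_stratum",
    "rank_top",
]

Z_95 = 1.96  # two-sided 95% normal quantile, as conventionally fixed


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a/b/c/d for one (vaccine, PT) pair."""

    a: int  # target reports listing the PT
    b: int  # target reports not listing it
    c: int  # comparator reports listing the PT
    d: int  # comparator reports not listing it

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class RorEstimate:
    """ROR point estimate with Wald 95% CI; NaN fields when undefined."""

    ror: float
    se_log: float
    ci_low: float
    ci_high: float
    is_signal: bool
    undefined: bool = False


@dataclass(frozen=True)
class SignalResult:
    """One PT's screen result within one stratum."""

    preferred_term: str
    stratum: str
    a: int
    frequency_per_100k: int
    ror: float
    se_log: float
    ci_low: float
    ci_high: float
    is_signal: bool
    undefined: bool = False


def build_contingency(
    long_table: pd.DataFrame,
    target_ids: Collection[str],
    comparator_ids: Collection[str],
    pt: str,
) -> ContingencyTable:
    """Count the 2x2 table for ``pt`` from the long (report_id, PT) table.

    ``target_ids`` and ``comparator_ids`` must be disjoint — an overlap
    would double-count reports across the margins.
    """
    target_ids = set(target_ids)
    comparator_ids = set(comparator_ids)
    overlap = target_ids & comparator_ids
    if overlap:
        raise ValueError(
            f"target and comparator id sets overlap ({len(overlap)} report(s))"
        )
    with_pt = set(
        long_table.loc[long_table["preferred_term"] == pt, "report_id"].unique()
    )
    a = len(with_pt & target_ids)
    c = len(with_pt & comparator_ids)
    return ContingencyTable(a=a, b=len(target_ids) - a, c=c, d=len(comparator_ids) - c)


def compute_ror(
    table: ContingencyTable,
    continuity_correction: bool = False,
    rule: str = "ci",
) -> RorEstimate:
    """ROR, Wald SE on the log scale, 95% CI and the signal flag.

    A zero cell makes the Wald estimate undefined: by default the result is
    marked ``undefined`` (and excluded from signal lists); with
    ``continuity_correction=True`` the Haldane–Anscombe +0.5 is added to all
    four cells instead.  ``rule`` selects the signal criterion: ``"ci"``
    (default) flags when ``ci_low > 1``; ``"literal"`` flags when
    ``ror - 1.96 * se_log > 1``, an alternative arithmetic reading of the
    same threshold kept for comparability.
    """
    if rule not in ("ci", "literal"):
        raise ValueError(f"unknown signal rule {rule!r}")
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0.0:
        if not continuity_correction:
            logger.info("zero cell in %s; ROR undefined (no continuity correction)", table)
            return RorEstimate(math.nan, math.nan, math.nan, math.nan, False, undefined=True)
        logger.info("zero cell in %s; applying Haldane-Anscombe +0.5", table)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se_log = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci_low = math.exp(math.log(ror) - Z_95 * se_log)
    ci_high = math.exp(math.log(ror) + Z_95 * se_log)
    if rule == "ci":
        is_signal = ci_low > 1.0
    else:
        is_signal = (ror - Z_95 * se_log) > 1.0
    return RorEstimate(ror, se_log, ci_low, ci_high, is_signal)


def normalized_frequency(a: int, n_total: int) -> int:
    """Reports-per-100,000 normalization, rounded half-up to an integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= a <= n_total:
        raise ValueError("count must lie in [0, n_total]")
    return int(round_half_up_ratio(a * 100_000, n_total, 0))


def screen_stratum(
    long_table: pd.DataFrame,
    target_ids: Collection[str],
    comparator_ids: Collection[str],
    stratum: str = "",
    stratum_denominator: int | None = None,
    continuity_correction: bool = False,
    rule: str = "ci",
) -> list[SignalResult]:
    """Screen every PT occurring in the target stratum.

    Returns one :class:`SignalResult` per PT, ordered by report count
    descending then PT ascending.  ``stratum_denominator`` defaults to the
    stratum size ``|target_ids|`` — per-100k frequencies for a subgroup
    screen are relative to that subgroup, not the whole cohort.
    """
    target_ids = set(target_ids)
    comparator_ids = set(comparator_ids)
    if target_ids & comparator_ids:
        raise ValueError("target and comparator id sets overlap")
    denom = len(target_ids) if stratum_denominator is None else stratum_denominator
    sub = long_table[long_table["report_id"].isin(target_ids)]
    comp = long_table[long_table["report_id"].isin(comparator_ids)]
    a_counts = sub.groupby("preferred_term")["report_id"].nunique()
    c_counts = comp.groupby("preferred_term")["report_id"].nunique()
    results: list[SignalResult] = []
    for pt, a in a_counts.items():
        a = int(a)
        c = int(c_counts.get(pt, 0))
        table = ContingencyTable(
            a=a, b=len(target_ids) - a, c=c, d=len(comparator_ids) - c
        )
        est = compute_ror(table, continuity_correction=continuity_correction, rule=rule)
        results.append(
            SignalResult(
                preferred_term=str(pt),
                stratum=stratum,
                a=a,
                frequency_per_100k=normalized_frequency(a, denom) if denom else 0,
                ror=est.ror,
                se_log=est.se_log,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                is_signal=est.is_signal,
                undefined=est.undefined,
            )
        )
    results.sort(key=lambda r: (-r.a, r.preferred_term))
    return results


def rank_top(results: Sequence[SignalResult], k: int = 10) -> list[SignalResult]:
    """Top-k PTs by report count, ties broken by PT ascending."""
    if k <= 0:
        raise ValueError("k must be positive")
    ordered = sorted(results, key=lambda r: (-r.a, r.preferred_term))
    return ordered[:k]


def format_ror_ci(result: SignalResult, star_signals: bool = False) -> str:
    """Publication-style ``ROR (lo - hi)`` string, 2 decimals, '*' for signals."""
    if result.undefined:
        return "NA"
    text = f"{result.ror:.2f} ({result.ci_low:.2f} - {result.ci_high:.2f})"
    if star_signals and result.is_signal:
        text = "*" + text
    return text


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Screen results as a Table-3-shaped frame."""
    return pd.DataFrame(
        {
            "Group": [r.stratum for r in results],
            "PT": [r.preferred_term for r in results],
            "All": [r.a for r in results],
            "Frequency": [r.frequency_per_100k for r in results],
            "ROR(95%CI)": [format_ror_ci(r) for r in results],
            "ror": [r.ror for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "is_signal": [r.is_signal for r in results],
        }
    )
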