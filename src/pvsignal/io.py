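"""Readers for VAERS-dialect CSV triplets and assembly into analysis tables.

VAERS distributes each year as three CSV files keyed by ``VAERS_ID``:

* ``VAERSDATA`` — one row per report: demographics, receive/vaccination/onset
  dates, the 21 CFR 600.80 seriousness outcome flags, and ``NUMDAYS`` (days
  from vaccination to symptom onset);
* ``VAERSSYMPTOMS`` — up to five MedDRA Preferred Terms (PTs) per row, with
  extra rows continuing the list when a report carries more than five;
* ``VAERSVAX`` — one row per administered vaccine (co-administration yields
  several rows per report).

This module parses those files leniently (the archives mix encodings,
casings and blank conventions across years), joins them on ``VAERS_ID`` and
emits two canonical tables: a report-level table (one row per de-duplicated
report) and a long report x PT table with ``(report_id, preferred_term)``
de-duplicated — the counting unit every downstream 2x2 table relies on.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import canonicalize_pt, logger, pt_key

__all__ = [
    "ConfigurationError",
    "RawDataRow",
    "RawSymptomRow",
    "RawVaxRow",
    "ReportRecord",
    "SymptomAssignment",
    "read_data_file",
    "read_symptoms_file",
    "read_vax_file",
    "assemble",
    "reports_to_frame",
    "assignments_to_frame",
]


class ConfigurationError(ValueError):
    """Raised when an input file or config does not match the expected layout."""


DATA_COLUMNS = [
    "VAERS_ID", "RECVDATE", "AGE_YRS", "SEX", "DIED", "L_THREAT", "HOSPITAL",
    "X_STAY", "DISABLE", "BIRTH_DEFECT", "NUMDAYS", "VAX_DATE", "ONSET_DATE",
]
SYMPTOM_COLUMNS = ["VAERS_ID"] + [f"SYMPTOM{i}" for i in range(1, 6)]
SYMPTOM_VERSION_COLUMNS = [f"SYMPTOMVERSION{i}" for i in range(1, 6)]
VAX_COLUMNS = ["VAERS_ID", "VAX_TYPE", "VAX_NAME"]


@dataclass
class RawDataRow:
    """One VAERSDATA row after parsing; blanks become missing/false."""

    report_id: str
    receive_date: dt.date | None = None
    age_years: float | None = None
    sex: str = "U"
    died: bool = False
    life_threat: bool = False
    hospitalized: bool = False
    hosp_prolonged: bool = False
    disabled: bool = False
    birth_defect: bool = False
    onset_interval_days: int | None = None
    vax_date: dt.date | None = None
    onset_date: dt.date | None = None


@dataclass
class RawSymptomRow:
    """One VAERSSYMPTOMS row: 1-5 PTs plus their MedDRA version strings."""

    report_id: str
    pts: list[str] = field(default_factory=list)
    meddra_versions: list[str] = field(default_factory=list)


@dataclass
class RawVaxRow:
    report_id: str
    vax_type: str = ""
    vax_name: str = ""
    dose: str | None = None
    route: str | None = None
    site: str | None = None


@dataclass
class ReportRecord:
    """One assembled, de-duplicated report with derived seriousness."""

    report_id: str
    receive_date: dt.date | None
    age_years: float | None
    sex: str
    serious: bool
    death: bool
    onset_interval_days: int | None
    vaccine_codes: set[str]


@dataclass(frozen=True)
class SymptomAssignment:
    """One (report, Preferred Term) pair; unique per report after de-dup."""

    report_id: str
    preferred_term: str


# ---------------------------------------------------------------------------
# low-level parsing helpers


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a VAERS CSV as strings, UTF-8 with Latin-1 fallback."""
    path = Path(path)
    kwargs = dict(dtype=str, keep_default_na=False, quoting=csv.QUOTE_MINIMAL)
    try:
        df = pd.read_csv(path, encoding="utf-8", **kwargs)
    except UnicodeDecodeError:
        logger.warning("%s is not valid UTF-8; falling back to Latin-1", path.name)
        df = pd.read_csv(path, encoding="latin-1", **kwargs)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    return df


def _parse_date(text: str) -> dt.date | None:
    """VAERS exports use the US month/day/year dialect; unparseable -> missing."""
    text = text.strip()
    if not text:
        return None
    for fmt in ("%m/%d/%Y", "%m/%d/%y", "%Y-%m-%d"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def _parse_flag(text: str) -> bool:
    """Seriousness outcome cells hold 'Y' or blank; blank means false."""
    return text.strip().upper() == "Y"


def _parse_nonneg(text: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return value if value >= 0 else None


def _dedupe_ids(ids: Iterable[str], filename: str) -> set[str]:
    seen: set[str] = set()
    dupes = 0
    for rid in ids:
        if rid in seen:
            dupes += 1
        seen.add(rid)
    if dupes:
        logger.warning("%s: %d duplicate VAERS_ID row(s); keeping first", filename, dupes)
    return seen


# ---------------------------------------------------------------------------
# file readers


def read_data_file(path: str | Path) -> list[RawDataRow]:
    """Parse a VAERSDATA file into :class:`RawDataRow` records.

    Blank seriousness cells parse as false, unparseable or negative ages and
    day counts as missing (counted and logged).  A duplicate ``VAERS_ID``
    within the file keeps the first row.
    """
    df = _read_csv(path, DATA_COLUMNS)
    name = Path(path).name
    rows: list[RawDataRow] = []
    seen: set[str] = set()
    n_bad_age = n_bad_days = n_dupe = 0
    for rec in df.to_dict("records"):
        rid = rec["VAERS_ID"].strip()
        if not rid:
            continue
        if rid in seen:
            n_dupe += 1
            continue
        seen.add(rid)
        age_text = rec["AGE_YRS"].strip()
        age = _parse_nonneg(rec["AGE_YRS"])
        if age is None and age_text:
            n_bad_age += 1
        days_text = rec["NUMDAYS"].strip()
        days = _parse_nonneg(rec["NUMDAYS"])
        if days is None and days_text:
            n_bad_days += 1
        sex = rec["SEX"].strip().upper() or "U"
        if sex not in {"F", "M"}:
            sex = "U"
        rows.append(
            RawDataRow(
                report_id=rid,
                receive_date=_parse_date(rec["RECVDATE"]),
                age_years=age,
                sex=sex,
                died=_parse_flag(rec["DIED"]),
                life_threat=_parse_flag(rec["L_THREAT"]),
                hospitalized=_parse_flag(rec["HOSPITAL"]),
                hosp_prolonged=_parse_flag(rec["X_STAY"]),
                disabled=_parse_flag(rec["DISABLE"]),
                birth_defect=_parse_flag(rec["BIRTH_DEFECT"]),
                onset_interval_days=None if days is None else int(days),
                vax_date=_parse_date(rec["VAX_DATE"]),
                onset_date=_parse_date(rec["ONSET_DATE"]),
            )
        )
    if n_dupe:
        logger.warning("%s: %d duplicate VAERS_ID row(s); kept first", name, n_dupe)
    if n_bad_age:
        logger.warning("%s: %d invalid AGE_YRS value(s) treated as missing", name, n_bad_age)
    if n_bad_days:
        logger.warning("%s: %d invalid NUMDAYS value(s) treated as missing", name, n_bad_days)
    return rows


def read_symptoms_file(path: str | Path) -> list[RawSymptomRow]:
    """Parse a VAERSSYMPTOMS file; blank PT cells are dropped.

    VAERS continues a report's PT list on extra rows, so several rows per
    ``VAERS_ID`` are expected and all are kept.  A row whose five PT cells
    are all blank is skipped with a warning.
    """
    df = _read_csv(path, SYMPTOM_COLUMNS)
    name = Path(path).name
    has_versions = all(c in df.columns for c in SYMPTOM_VERSION_COLUMNS)
    rows: list[RawSymptomRow] = []
    n_empty = 0
    for rec in df.to_dict("records"):
        rid = rec["VAERS_ID"].strip()
        if not rid:
            continue
        pts: list[str] = []
        versions: list[str] = []
        for i in range(1, 6):
            term = canonicalize_pt(rec[f"SYMPTOM{i}"])
            if term:
                pts.append(term)
                versions.append(rec[f"SYMPTOMVERSION{i}"].strip() if has_versions else "")
        if not pts:
            n_empty += 1
            continue
        rows.append(RawSymptomRow(report_id=rid, pts=pts, meddra_versions=versions))
    if n_empty:
        logger.warning("%s: %d symptom row(s) with no PT skipped", name, n_empty)
    return rows


def read_vax_file(path: str | Path) -> list[RawVaxRow]:
    """Parse a VAERSVAX file; one report may carry several vaccine rows."""
    df = _read_csv(path, VAX_COLUMNS)
    rows: list[RawVaxRow] = []
    for rec in df.to_dict("records"):
        rid = rec["VAERS_ID"].strip()
        if not rid:
            continue
        rows.append(
            RawVaxRow(
                report_id=rid,
                vax_type=rec["VAX_TYPE"].strip(),
                vax_name=rec["VAX_NAME"].strip(),
                dose=rec.get("VAX_DOSE_SERIES", "").strip() or None,
                route=rec.get("VAX_ROUTE", "").strip() or None,
                site=rec.get("VAX_SITE", "").strip() or None,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# assembly


def _resolve_onset(row: RawDataRow) -> int | None:
    """NUMDAYS wins; fall back to ONSET_DATE - VAX_DATE when both dates parse."""
    derived: int | None = None
    if row.vax_date is not None and row.onset_date is not None:
        delta = (row.onset_date - row.vax_date).days
        if delta >= 0:
            derived = delta
    if row.onset_interval_days is not None:
        if derived is not None and derived != row.onset_interval_days:
            logger.warning(
                "report %s: NUMDAYS=%d disagrees with date difference %d; keeping NUMDAYS",
                row.report_id, row.onset_interval_days, derived,
            )
        return row.onset_interval_days
    return derived


def assemble(
    data_rows: Sequence[RawDataRow],
    symptom_rows: Sequence[RawSymptomRow],
    vax_rows: Sequence[RawVaxRow],
) -> tuple[list[ReportRecord], list[SymptomAssignment]]:
    """Inner-join the three file types into report-level and long tables.

    Reports missing a data row, a vaccine row or any PT are dropped (counts
    logged); ``(report_id, PT)`` pairs are de-duplicated case-insensitively,
    keeping the first-seen casing; duplicate data rows for one report keep
    the earliest ``receive_date``.  ``serious`` is derived from the outcome
    flags via :func:`pvsignal.cohort.classify_serious` and death implies
    serious by construction.
    """
    from .cohort import classify_serious  # local import: cohort is flag-only, no cycle

    by_id: dict[str, RawDataRow] = {}
    for row in data_rows:
        prev = by_id.get(row.report_id)
        if prev is None:
            by_id[row.report_id] = row
        else:
            # duplicate across yearly/domestic files: keep earliest receive_date
            pk = (prev.receive_date or dt.date.max, )
            rk = (row.receive_date or dt.date.max, )
            if rk < pk:
                by_id[row.report_id] = row
            logger.warning("duplicate data row for report %s; keeping first by receive date",
                           row.report_id)

    pts_by_id: dict[str, dict[str, str]] = {}
    for srow in symptom_rows:
        bucket = pts_by_id.setdefault(srow.report_id, {})
        for term in srow.pts:
            bucket.setdefault(pt_key(term), term)

    vax_by_id: dict[str, set[str]] = {}
    for vrow in vax_rows:
        codes = vax_by_id.setdefault(vrow.report_id, set())
        if vrow.vax_type:
            codes.add(vrow.vax_type)
        if vrow.vax_name:
            codes.add(vrow.vax_name)

    reports: list[ReportRecord] = []
    assignments: list[SymptomAssignment] = []
    n_no_data = len(set(pts_by_id) - set(by_id))
    n_no_pt = n_no_vax = 0
    for rid, row in by_id.items():
        pts = pts_by_id.get(rid)
        if not pts:
            n_no_pt += 1
            continue
        codes = vax_by_id.get(rid)
        if not codes:
            n_no_vax += 1
            continue
        serious = classify_serious(row)
        reports.append(
            ReportRecord(
                report_id=rid,
                receive_date=row.receive_date,
                age_years=row.age_years,
                sex=row.sex,
                serious=serious,
                death=row.died,
                onset_interval_days=_resolve_onset(row),
                vaccine_codes=codes,
            )
        )
        assignments.extend(
            SymptomAssignment(report_id=rid, preferred_term=term) for term in pts.values()
        )
    for label, n in (("no data row", n_no_data), ("no PT", n_no_pt), ("no vaccine row", n_no_vax)):
        if n:
            logger.info("assemble: dropped %d report(s) with %s", n, label)
    return reports, assignments


def reports_to_frame(reports: Sequence[ReportRecord]) -> pd.DataFrame:
    """Report-level table; vaccine codes joined with ';' for TSV round-trips."""
    return pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "receive_date": [r.receive_date for r in reports],
            "age_years": [r.age_years for r in reports],
            "sex": [r.sex for r in reports],
            "serious": [r.serious for r in reports],
            "death": [r.death for r in reports],
            "onset_interval_days": [r.onset_interval_days for r in reports],
            "vaccine_codes": [";".join(sorted(r.vaccine_codes)) for r in reports],
        }
    )


def assignments_to_frame(assignments: Sequence[SymptomAssignment]) -> pd.DataFrame:
    """Long (report_id, preferred_term) table — the PT counting unit."""
    return pd.DataFrame(
        {
            "report_id": [a.report_id for a in assignments],
            "preferred_term": [a.preferred_term for a in assignments],
        }
    )
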