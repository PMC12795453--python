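"""System Organ Class (SOC) aggregation of Preferred-Term counts.

MedDRA's top hierarchy level groups PTs by organ system.  The dictionary
itself is licensed, so the PT -> SOC mapping is user-supplied as a
two-column delimited file; a small mapping covering the PTs this package's
synthetic data emits ships with the test suite.

The counting unit is PT *occurrences* (report x PT pairs), not reports: a
report listing three nervous-system PTs contributes three to that SOC, so
SOC totals exceed the report count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Mapping

import pandas as pd

from ._util import canonicalize_pt, logger, pt_key, round_half_up_ratio

__all__ = ["SocMapping", "SocDistribution", "load_soc_mapping", "soc_distribution"]

UNMAPPED = "Unmapped"


@dataclass(frozen=True)
class SocMapping:
    """Case-insensitive PT -> SOC lookup built from a two-column table."""

    _by_key: Mapping[str, str]

    def get(self, preferred_term: str) -> str | None:
        return self._by_key.get(pt_key(preferred_term))

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, preferred_term: str) -> bool:
        return pt_key(preferred_term) in self._by_key


@dataclass(frozen=True)
class SocDistribution:
    """Per-SOC occurrence counts and percentages of all mapped occurrences."""

    counts: dict[str, int]
    percents: dict[str, float]
    total_mapped: int
    n_unmapped: int


def load_soc_mapping(path: str | Path, sep: str = "\t") -> SocMapping:
    """Load a (PT, SOC) two-column file; PT keys are canonicalized.

    Duplicate rows that agree are collapsed; a PT mapped to two different
    SOCs is a data error and raises with the conflicting terms listed.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (PT, SOC)")
    by_key: dict[str, str] = {}
    conflicts: list[str] = []
    for pt, soc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        term = canonicalize_pt(pt)
        soc = soc.strip()
        if not term:
            continue
        key = pt_key(term)
        if key in by_key and by_key[key] != soc:
            conflicts.append(term)
        else:
            by_key[key] = soc
    if conflicts:
        raise ValueError(
            f"{path}: conflicting SOC assignments for PT(s): {', '.join(sorted(set(conflicts)))}"
        )
    if not by_key:
        logger.warning("%s: empty SOC mapping", path)
    return SocMapping(by_key)


def soc_distribution(
    long_table: pd.DataFrame,
    stratum_ids: Collection[str],
    mapping: SocMapping,
) -> SocDistribution:
    """Distribute a stratum's PT occurrences over SOCs.

    Percentages are of *mapped* occurrences, half-up to 2 decimals;
    unmapped PTs pool under ``"Unmapped"`` (excluded from the percentage
    denominator) and the distinct unmapped terms are logged.
    """
    sub = long_table[long_table["report_id"].isin(set(stratum_ids))]
    counts: dict[str, int] = {}
    n_unmapped = 0
    unmapped_terms: set[str] = set()
    for term in sub["preferred_term"]:
        soc = mapping.get(term)
        if soc is None:
            n_unmapped += 1
            unmapped_terms.add(term)
        else:
            counts[soc] = counts.get(soc, 0) + 1
    if unmapped_terms:
        logger.warning(
            "soc_distribution: %d occurrence(s) of unmapped PT(s): %s",
            n_unmapped, ", ".join(sorted(unmapped_terms)),
        )
    total = sum(counts.values())
    percents = {
        soc: round_half_up_ratio(cnt * 10_000, total, 0) / 100 if total else 0.0
        for soc, cnt in counts.items()
    }
    return SocDistribution(
        counts=counts, percents=percents, total_mapped=total, n_unmapped=n_unmapped
    )


# Toy PT -> SOC table covering every PT the synthetic generator can emit,
# so the full pipeline runs without the licensed MedDRA dictionary.  SOC
# assignments follow MedDRA naming conventions but are NOT the licensed
# hierarchy; real analyses must supply their own mapping file.
TOY_PT_SOC: dict[str, str] = {
    "Crying": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Chills": "General disorders and administration site conditions",
    "Malaise": "General disorders and administration site conditions",
    "Pain": "General disorders and administration site conditions",
    "Swelling": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Peripheral swelling": "General disorders and administration site conditions",
    "Injection site erythema": "General disorders and administration site conditions",
    "Injection site swelling": "General disorders and administration site conditions",
    "Vaccination site nodule": "General disorders and administration site conditions",
    "Vaccination site reaction": "General disorders and administration site conditions",
    "Vaccination site oedema": "General disorders and administration site conditions",
    "Vomiting": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Melaena": "Gastrointestinal disorders",
    "Apnoea": "Respiratory, thoracic and mediastinal disorders",
    "Bronchiolitis": "Infections and infestations",
    "Somnolence": "Nervous system disorders",
    "Seizure": "Nervous system disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Gait disturbance": "Nervous system disorders",
    "Hypotonia": "Nervous system disorders",
    "Hypotonic-hyporesponsive episode": "Nervous system disorders",
    "Pallor": "Vascular disorders",
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Restlessness": "Psychiatric disorders",
    "Irritability": "Psychiatric disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Urticaria": "Skin and subcutaneous tissue disorders",
    "Erythema": "Skin and subcutaneous tissue disorders",
    "Pain in extremity": "Musculoskeletal and connective tissue disorders",
}


def toy_mapping() -> SocMapping:
    """The bundled toy PT -> SOC mapping as a :class:`SocMapping`."""
    return SocMapping({pt_key(pt): soc for pt, soc in TOY_PT_SOC.items()})


def soc_table(dist: SocDistribution) -> pd.DataFrame:
    """Table-4-shaped frame, SOCs sorted by count descending then name."""
    socs = sorted(dist.counts, key=lambda s: (-dist.counts[s], s))
    rows = [{"SOC": s, "TOTAL": dist.counts[s], "Per(%)": dist.percents[s]} for s in socs]
    if dist.n_unmapped:
        rows.append({"SOC": UNMAPPED, "TOTAL": dist.n_unmapped, "Per(%)": float("nan")})
    return pd.DataFrame(rows, columns=["SOC", "TOTAL", "Per(%)"])
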