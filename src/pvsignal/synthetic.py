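"""Seeded generator of VAERS-format report triplets with known ground truth.

Real spontaneous-report archives cannot ship with a package, so every
pipeline stage is exercised against synthetic triplet files whose latent
structure is known exactly.  The generator emulates the marginals of a
pediatric pneumococcal-vaccine report population:

* ~49% of reports serious (21 CFR 600.80 outcome flags), deaths a small
  subset of serious reports at per-vaccine rates;
* an infant-dominated age mixture (most reports at ages 0-1, small 2-10 and
  adult components, an empty 11-18 bin, and a large age-unknown share);
* 1-5 Preferred Terms per report with age-group-specific PT profiles;
* onset delays concentrated at 0-1 days with a long geometric tail (so the
  mean far exceeds the median), ~18% missing;
* sex recorded as F/M/unknown with ~25% unknown.

Four *signal PTs* (hypotonic-hyporesponsive episode, hypotonia, pallor,
bronchiolitis) are drawn per report as independent Bernoulli events whose
probability is vaccine-specific.  A ``true_ror_overrides`` entry multiplies
the target vaccine's odds for that PT relative to the base probability, so
the report-level reporting odds ratio against any cohort generated at the
base rate equals the override exactly; the truth record stores the expected
ROR of every signal PT computed in closed form from the generating
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AGE_GROUP_LABELS

__all__ = [
    "GeneratorConfig",
    "GeneratedData",
    "TruthRecord",
    "generate",
    "write_fixture",
    "DEFAULT_N_REPORTS",
    "SIGNAL_PTS",
]

# Per-vaccine report totals of the study's comparison set, plus a generic
# background cohort standing in for the rest of the reporting universe.
DEFAULT_N_REPORTS: dict[str, int] = {
    "SYNFLORIX": 1704,
    "PREVNAR": 6074,
    "PREVNAR13": 43273,
    "VAXNEUVANCE": 1034,
    "PREVNAR20": 4350,
    "PNEUMOVAX": 49647,
    "OTHER": 50000,
}

VAX_TYPE_CODES = {
    "SYNFLORIX": "PNC10", "PREVNAR": "PNC", "PREVNAR13": "PNC13",
    "VAXNEUVANCE": "PNC15", "PREVNAR20": "PNC20", "PNEUMOVAX": "PPV",
    "OTHER": "OTH",
}

SIGNAL_PTS = (
    "Hypotonic-hyporesponsive episode",
    "Hypotonia",
    "Pallor",
    "Bronchiolitis",
)

# Background (non-signal) occurrence probabilities of the signal PTs.
DEFAULT_SIGNAL_BASE_PROBS: dict[str, float] = {
    "Hypotonic-hyporesponsive episode": 0.0005,
    "Hypotonia": 0.002,
    "Pallor": 0.004,
    "Bronchiolitis": 0.0005,
}

# Per-vaccine reporting rates (reports with the PT / all reports of that
# vaccine) of the signal PTs and of death outcomes in the emulated
# surveillance population.
DEFAULT_SIGNAL_RATES: dict[str, dict[str, float]] = {
    "SYNFLORIX": {"Hypotonic-hyporesponsive episode": 0.17723, "Hypotonia": 0.08509,
                  "Pallor": 0.09155, "Bronchiolitis": 0.04167},
    "PREVNAR": {"Hypotonic-hyporesponsive episode": 0.01416, "Hypotonia": 0.04610,
                "Pallor": 0.05663, "Bronchiolitis": 0.00280},
    "PREVNAR13": {"Hypotonic-hyporesponsive episode": 0.00996, "Hypotonia": 0.02572,
                  "Pallor": 0.03092, "Bronchiolitis": 0.00178},
    "VAXNEUVANCE": {"Hypotonic-hyporesponsive episode": 0.00580, "Hypotonia": 0.01547,
                    "Pallor": 0.01838, "Bronchiolitis": 0.00097},
    "PREVNAR20": {"Hypotonic-hyporesponsive episode": 0.00046, "Hypotonia": 0.00322,
                  "Pallor": 0.00897, "Bronchiolitis": 0.00046},
    "PNEUMOVAX": {"Hypotonic-hyporesponsive episode": 0.00010, "Hypotonia": 0.00054,
                  "Pallor": 0.00254, "Bronchiolitis": 0.00056},
}

DEFAULT_DEATH_RATES: dict[str, float] = {
    "SYNFLORIX": 0.01937, "PREVNAR": 0.03161, "PREVNAR13": 0.02500,
    "VAXNEUVANCE": 0.01838, "PREVNAR20": 0.00989, "PNEUMOVAX": 0.00512,
    "OTHER": 0.01000,
}

# Background PT catalog: relative sampling weight per age group
# (0-1, 2-10, 11-18, 19-54, >=55, unknown).  Infants skew to systemic
# reactions, adults to injection-site reactions; the unknown-age group
# mirrors infants since most age-missing pediatric reports are infants.
DEFAULT_BACKGROUND_PTS: dict[str, tuple[float, float, float, float, float, float]] = {
    "Crying":                    (20.0, 6.0, 1.0, 0.1, 0.1, 18.0),
    "Pyrexia":                   (18.0, 8.0, 4.0, 3.0, 3.0, 16.0),
    "Vomiting":                  (6.0, 3.0, 2.0, 1.0, 0.5, 5.0),
    "Diarrhoea":                 (5.0, 2.0, 1.0, 0.5, 0.5, 4.0),
    "Apnoea":                    (3.0, 0.5, 0.2, 0.1, 0.1, 2.5),
    "Somnolence":                (4.0, 1.5, 1.0, 0.5, 0.5, 3.5),
    "Decreased appetite":        (4.0, 1.5, 0.5, 0.3, 0.3, 3.5),
    "Restlessness":              (4.0, 1.0, 0.5, 0.3, 0.2, 3.5),
    "Irritability":              (3.0, 1.0, 0.5, 0.2, 0.2, 2.5),
    "Rash":                      (2.0, 1.5, 1.0, 0.8, 0.8, 2.0),
    "Urticaria":                 (1.0, 1.0, 0.8, 0.6, 0.5, 1.0),
    "Seizure":                   (1.5, 0.8, 0.3, 0.1, 0.1, 1.2),
    "Injection site erythema":   (1.0, 2.5, 2.0, 3.0, 4.0, 1.0),
    "Injection site swelling":   (0.8, 2.0, 2.0, 3.5, 3.0, 0.8),
    "Erythema":                  (1.0, 1.5, 1.5, 3.5, 4.5, 1.0),
    "Swelling":                  (0.5, 1.0, 1.0, 2.0, 3.0, 0.5),
    "Pain in extremity":         (0.3, 2.0, 2.0, 3.0, 3.0, 0.3),
    "Headache":                  (0.1, 1.0, 2.0, 2.5, 1.5, 0.1),
    "Chills":                    (0.1, 0.5, 1.0, 2.0, 2.0, 0.1),
    "Malaise":                   (0.2, 0.8, 1.0, 2.5, 1.5, 0.2),
    "Gait disturbance":          (0.2, 2.0, 0.5, 0.3, 0.3, 0.2),
    "Vaccination site nodule":   (0.1, 1.2, 0.5, 0.5, 0.3, 0.1),
    "Vaccination site reaction": (0.2, 1.2, 0.5, 0.8, 0.5, 0.2),
    "Vaccination site oedema":   (0.1, 1.0, 0.3, 0.3, 0.2, 0.1),
    "Dizziness":                 (0.05, 0.3, 1.0, 1.5, 1.5, 0.05),
    "Pain":                      (0.2, 0.8, 1.0, 1.5, 1.5, 0.2),
    "Oedema peripheral":         (0.05, 0.2, 0.3, 1.2, 1.0, 0.05),
    "Peripheral swelling":       (0.05, 0.2, 0.3, 0.8, 1.2, 0.05),
}


def _odds(p: float) -> float:
    return p / (1.0 - p)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic report population; defaults are the study
    marginals (see docs/methods.md for provenance and choices)."""

    seed: int = 0
    n_reports: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_REPORTS))
    p_serious: float = 0.49
    death_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DEATH_RATES))
    default_death_rate: float = 0.01
    sex_probs: tuple[float, float, float] = (0.346, 0.400, 0.254)  # F, M, U
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: {
            "0-1": 1054 / 1704, "2-10": 22 / 1704, "11-18": 0.0,
            "19-54": 13 / 1704, ">=55": 19 / 1704, "unknown": 596 / 1704,
        }
    )
    pts_per_report: tuple[float, ...] = (0.15, 0.20, 0.25, 0.20, 0.20)  # P(K=1..5)
    background_pts: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_PTS)
    )
    signal_base_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_BASE_PROBS)
    )
    true_ror_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    onset_point_mass: float = 0.70      # P(onset in {0, 1})
    onset_p_zero_within: float = 0.78   # P(onset = 0 | point mass)
    onset_tail_mean: float = 31.0       # geometric tail mean, days
    p_onset_missing: float = 0.178
    date_window: tuple[str, str] = ("2010-01-01", "2024-12-30")
    casing_noise: bool = False  # perturb PT casing/whitespace to stress canonicalization

    def __post_init__(self) -> None:
        if not self.true_ror_overrides:
            # default calibration: per-vaccine signal-PT rates of the
            # emulated population, expressed as odds multipliers vs base
            overrides: dict[tuple[str, str], float] = {}
            for vax, rates in DEFAULT_SIGNAL_RATES.items():
                if vax not in self.n_reports:
                    continue
                for pt, rate in rates.items():
                    base = self.signal_base_probs[pt]
                    overrides[(vax, pt)] = _odds(rate) / _odds(base)
            self.true_ror_overrides = overrides
        self.validate()

    def validate(self) -> None:
        if any(n < 0 for n in self.n_reports.values()):
            raise ValueError("n_reports must be non-negative")
        for name, p in [("p_serious", self.p_serious),
                        ("onset_point_mass", self.onset_point_mass),
                        ("onset_p_zero_within", self.onset_p_zero_within),
                        ("p_onset_missing", self.p_onset_missing)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ValueError("sex_probs must sum to 1")
        if abs(sum(self.age_group_probs.values()) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")
        if sum(self.pts_per_report) <= 0:
            raise ValueError("pts_per_report has zero total probability")
        if len(self.pts_per_report) != 5:
            raise ValueError("pts_per_report must give P(K=1)..P(K=5)")
        for pt, p in self.signal_base_probs.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"signal base probability for {pt} must be in (0, 1)")
        for (vax, pt), mult in self.true_ror_overrides.items():
            if mult <= 0:
                raise ValueError(f"override for {(vax, pt)} must be positive")
            if pt not in self.signal_base_probs:
                raise ValueError(f"override PT {pt!r} has no base probability")

    def signal_prob(self, vaccine: str, pt: str) -> float:
        """Per-report occurrence probability of a signal PT for one vaccine."""
        base = self.signal_base_probs[pt]
        mult = self.true_ror_overrides.get((vaccine, pt), 1.0)
        odds = _odds(base) * mult
        return odds / (1.0 + odds)

    def expected_ror(self, vaccine: str, pt: str) -> float:
        """Closed-form expected ROR of ``(vaccine, pt)`` against all other
        configured vaccines pooled (weighted by their report totals)."""
        p_t = self.signal_prob(vaccine, pt)
        rest = [(v, n) for v, n in self.n_reports.items() if v != vaccine and n > 0]
        n_rest = sum(n for _, n in rest)
        if n_rest == 0:
            raise ValueError("no comparator reports configured")
        p_c = sum(n * self.signal_prob(v, pt) for v, n in rest) / n_rest
        return _odds(p_t) / _odds(p_c)


@dataclass
class TruthRecord:
    """Latent per-report strata plus closed-form expected RORs."""

    reports: pd.DataFrame      # report_id, vaccine, age_group, serious, death, onset
    assignments: pd.DataFrame  # report_id, preferred_term (de-duplicated)
    expected_ror: dict[tuple[str, str], float]

    def expected_ror_frame(self) -> pd.DataFrame:
        rows = [
            {"vaccine": v, "preferred_term": pt, "expected_ror": r}
            for (v, pt), r in sorted(self.expected_ror.items())
        ]
        return pd.DataFrame(rows, columns=["vaccine", "preferred_term", "expected_ror"])


@dataclass
class GeneratedData:
    data: pd.DataFrame      # VAERSDATA dialect
    symptoms: pd.DataFrame  # VAERSSYMPTOMS dialect
    vax: pd.DataFrame       # VAERSVAX dialect
    truth: TruthRecord


# ---------------------------------------------------------------------------
# sampling internals (all vectorized; one numpy Generator drives everything)


def _sample_ages(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    ages = np.full(groups.shape, np.nan)
    m = groups == "0-1"
    if m.any():  # infant ages: lognormal around 3 months, clipped to the bin
        ages[m] = np.clip(rng.lognormal(np.log(0.25), 0.7, m.sum()), 0.01, 1.6)
    m = groups == "2-10"
    if m.any():
        ages[m] = rng.uniform(2.0, 8.0, m.sum())
    m = groups == "11-18"
    if m.any():
        ages[m] = rng.uniform(11.0, 18.0, m.sum())
    m = groups == "19-54"
    if m.any():
        ages[m] = rng.uniform(19.0, 53.0, m.sum())
    m = groups == ">=55"
    if m.any():
        ages[m] = rng.uniform(55.0, 88.0, m.sum())
    return np.round(ages, 2)


def _sample_onsets(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    in_mass = rng.random(n) < cfg.onset_point_mass
    mass_vals = (rng.random(n) >= cfg.onset_p_zero_within).astype(int)  # 0 or 1 day
    tail_vals = rng.geometric(1.0 / cfg.onset_tail_mean, n)
    return np.where(in_mass, mass_vals, tail_vals).astype(float)


def _sample_background(
    rng: np.random.Generator,
    group_idx: np.ndarray,
    n_bg: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sampling without replacement of n_bg[i] background PTs per
    report, via the Gumbel top-k trick (exact Plackett-Luce draws)."""
    n, n_pts = len(group_idx), weights.shape[1]
    with np.errstate(divide="ignore"):
        logw = np.log(weights)[group_idx]  # (n, n_pts)
    scores = logw + rng.gumbel(size=(n, n_pts))
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_pts)[None, :].repeat(n, 0), axis=1)
    chosen = ranks < n_bg[:, None]
    rows, cols = np.nonzero(chosen)
    return rows, cols


_FLAG_COLS = ["DIED", "L_THREAT", "HOSPITAL", "X_STAY", "DISABLE", "BIRTH_DEFECT"]
# among serious non-death reports, which outcome flag fires
_NONDEATH_FLAGS = ["HOSPITAL", "L_THREAT", "DISABLE", "X_STAY", "BIRTH_DEFECT"]
_NONDEATH_FLAG_P = [0.80, 0.10, 0.06, 0.02, 0.02]


def generate(config: GeneratorConfig) -> GeneratedData:
    """Draw one synthetic report population; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vaccines = [v for v in config.n_reports]
    counts = [config.n_reports[v] for v in vaccines]
    n = int(sum(counts))

    vaccine = np.repeat(np.array(vaccines, dtype=object), counts)
    report_id = np.array([str(1_000_001 + i) for i in range(n)], dtype=object)

    group_labels = np.array(AGE_GROUP_LABELS, dtype=object)
    group_p = np.array([config.age_group_probs.get(g, 0.0) for g in AGE_GROUP_LABELS])
    group_idx = rng.choice(len(group_labels), size=n, p=group_p / group_p.sum())
    groups = group_labels[group_idx]
    ages = _sample_ages(rng, groups)

    sex = np.array(["F", "M", "U"], dtype=object)[
        rng.choice(3, size=n, p=np.asarray(config.sex_probs))
    ]

    serious = rng.random(n) < config.p_serious
    death_rate = np.array([
        config.death_rates.get(v, config.default_death_rate) for v in vaccine
    ])
    p_death_given_serious = np.clip(death_rate / max(config.p_serious, 1e-12), 0.0, 1.0)
    death = serious & (rng.random(n) < p_death_given_serious)

    onset = _sample_onsets(rng, n, config)
    onset_missing = rng.random(n) < config.p_onset_missing

    # --- PT assignment ------------------------------------------------------
    signal_pts = list(config.signal_base_probs)
    sig_p = np.zeros((n, len(signal_pts)))
    for j, pt in enumerate(signal_pts):
        probs = {v: config.signal_prob(v, pt) for v in vaccines}
        sig_p[:, j] = np.array([probs[v] for v in vaccine])
    sig_hit = rng.random((n, len(signal_pts))) < sig_p
    n_sig = sig_hit.sum(axis=1)

    k = rng.choice(np.arange(1, 6), size=n,
                   p=np.asarray(config.pts_per_report) / sum(config.pts_per_report))
    n_bg = np.clip(k - n_sig, 0, 5 - n_sig)
    n_bg[(n_sig == 0) & (n_bg == 0)] = 1  # every report carries at least one PT

    bg_pts = list(config.background_pts)
    weights = np.array([config.background_pts[pt] for pt in bg_pts]).T  # (groups, pts)
    if weights.shape[0] != len(AGE_GROUP_LABELS):
        raise ValueError("background PT weights must give one value per age group")
    bg_rows, bg_cols = _sample_background(rng, group_idx, n_bg, weights)

    sig_rows, sig_cols = np.nonzero(sig_hit)
    all_rows = np.concatenate([sig_rows, bg_rows])
    all_terms = np.concatenate([
        np.array(signal_pts, dtype=object)[sig_cols],
        np.array(bg_pts, dtype=object)[bg_cols],
    ])
    order = np.argsort(all_rows, kind="stable")
    all_rows, all_terms = all_rows[order], all_terms[order]

    # --- dates --------------------------------------------------------------
    start = np.datetime64(config.date_window[0])
    end = np.datetime64(config.date_window[1])
    span = int((end - start) / np.timedelta64(1, "D"))
    recv = start + rng.integers(0, span + 1, size=n).astype("timedelta64[D]")
    vax_date = recv - rng.integers(1, 61, size=n).astype("timedelta64[D]")
    onset_date = vax_date + onset.astype(int).astype("timedelta64[D]")

    def fmt_dates(arr: np.ndarray) -> np.ndarray:
        out = pd.to_datetime(arr).strftime("%m/%d/%Y")
        return np.asarray(out, dtype=object)

    # --- VAERSDATA ----------------------------------------------------------
    data = pd.DataFrame({"VAERS_ID": report_id})
    data["RECVDATE"] = fmt_dates(recv)
    data["AGE_YRS"] = np.where(np.isnan(ages), "",
                               np.char.mod("%.2f", np.nan_to_num(ages)))
    data["SEX"] = sex
    nondeath_flag = np.array(_NONDEATH_FLAGS, dtype=object)[
        rng.choice(len(_NONDEATH_FLAGS), size=n, p=_NONDEATH_FLAG_P)
    ]
    for col in _FLAG_COLS:
        flagged = np.where(
            death, col == "DIED", serious & ~death & (nondeath_flag == col)
        )
        data[col] = np.where(flagged, "Y", "")
    data["NUMDAYS"] = np.where(onset_missing, "",
                               onset.astype(int).astype(str))
    data["VAX_DATE"] = fmt_dates(vax_date)
    data["ONSET_DATE"] = np.where(onset_missing, "", fmt_dates(onset_date))

    # --- VAERSSYMPTOMS (chunk each report's PTs into rows of five) ----------
    terms_out = all_terms
    if config.casing_noise and len(terms_out):
        styles = rng.choice(3, size=len(terms_out))
        terms_out = np.array([
            t.upper() if s == 0 else (t.lower() + " " if s == 1 else t)
            for t, s in zip(terms_out, styles)
        ], dtype=object)
    if len(all_rows):
        occ = np.arange(len(all_rows)) - np.searchsorted(all_rows, all_rows, side="left")
        chunk = occ // 5
        col = occ % 5
        keys = all_rows * (int(chunk.max()) + 1 if len(chunk) else 1) + chunk
        uniq_keys, row_of = np.unique(keys, return_inverse=True)
        sym_cells = np.full((len(uniq_keys), 5), "", dtype=object)
        sym_cells[row_of, col] = terms_out
        ver_cells = np.where(sym_cells == "", "", "27.0").astype(object)
        sym_ids = report_id[all_rows[np.searchsorted(keys, uniq_keys)]]
    else:
        sym_cells = np.empty((0, 5), dtype=object)
        ver_cells = np.empty((0, 5), dtype=object)
        sym_ids = np.empty(0, dtype=object)
    symptoms = pd.DataFrame({"VAERS_ID": sym_ids})
    for i in range(5):
        symptoms[f"SYMPTOM{i + 1}"] = sym_cells[:, i]
        symptoms[f"SYMPTOMVERSION{i + 1}"] = ver_cells[:, i]

    # --- VAERSVAX -----------------------------------------------------------
    vax = pd.DataFrame(
        {
            "VAERS_ID": report_id,
            "VAX_TYPE": [VAX_TYPE_CODES.get(v, str(v)[:6].upper()) for v in vaccine],
            "VAX_NAME": vaccine,
        }
    )

    # --- truth --------------------------------------------------------------
    truth_reports = pd.DataFrame(
        {
            "report_id": report_id,
            "vaccine": vaccine,
            "age_group": groups,
            "age_years": ages,
            "sex": sex,
            "serious": serious,
            "death": death,
            "onset_days": np.where(onset_missing, np.nan, onset),
        }
    )
    truth_assign = pd.DataFrame(
        {"report_id": report_id[all_rows], "preferred_term": all_terms}
    )
    expected = {
        (v, pt): config.expected_ror(v, pt)
        for (v, pt) in config.true_ror_overrides
        if config.n_reports.get(v, 0) > 0 and sum(
            m for vx, m in config.n_reports.items() if vx != v
        ) > 0
    }
    truth = TruthRecord(reports=truth_reports, assignments=truth_assign,
                        expected_ror=expected)
    return GeneratedData(data=data, symptoms=symptoms, vax=vax, truth=truth)


def write_fixture(generated: GeneratedData, directory: str | Path) -> dict[str, Path]:
    """Write the triplet CSVs (VAERS dialect) plus truth TSVs; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": directory / "VAERSDATA.csv",
        "symptoms": directory / "VAERSSYMPTOMS.csv",
        "vax": directory / "VAERSVAX.csv",
        "truth_reports": directory / "truth_reports.tsv",
        "truth_ror": directory / "truth_ror.tsv",
    }
    generated.data.to_csv(paths["data"], index=False, lineterminator="\n")
    generated.symptoms.to_csv(paths["symptoms"], index=False, lineterminator="\n")
    generated.vax.to_csv(paths["vax"], index=False, lineterminator="\n")
    generated.truth.reports.to_csv(paths["truth_reports"], sep="\t", index=False,
                                   lineterminator="\n")
    generated.truth.expected_ror_frame().to_csv(paths["truth_ror"], sep="\t",
                                                index=False, lineterminator="\n")
    return paths
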