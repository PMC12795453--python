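# Methods

## The analysis model

`pvsignal` implements frequentist disproportionality analysis for
spontaneous-report databases in the VAERS triplet dialect. The unit of
analysis is the *report*: after joining the DATA / SYMPTOMS / VAX files on
report id, each report contributes at most one occurrence of each MedDRA
Preferred Term (PT), whatever the number of symptom rows that mention it.
For a target cohort T and a disjoint comparator universe C, each PT yields
the 2×2 table a = |T with PT|, b = |T without|, c = |C with|,
d = |C without|, and

    ROR = ad / bc,
    SE(ln ROR) = √(1/a + 1/b + 1/c + 1/d),
    95% CI = exp(ln ROR ± 1.96 · SE(ln ROR)).

A PT is flagged as a signal when the CI lower bound exceeds 1. The Wald
interval is asymptotic; its coverage is verified empirically in the test
suite (see "Problem sizes" below) rather than assumed. The estimator
assumes independent reports and a comparator free of the target's reports —
`build_contingency` rejects overlapping id sets outright because an overlap
silently double-counts margins.

Assumptions inherited from passive surveillance: reporting is voluntary and
selective, there is no population denominator, and disproportion is a
property of the *reporting stream*, not of incidence. Nothing in the
package estimates risk or supports causal claims.

### Signal rule variants

The CI-bound rule (`rule="ci"`) is the default and the standard form
consistent with the log-scale CI. An alternative arithmetic reading,
`ROR − 1.96·SE(ln ROR) > 1` (`rule="literal"`), circulates in applied work;
it is exposed as a documented flag so results under either reading can be
compared, but it mixes scales (a natural-scale point estimate with a
log-scale SE) and is not recommended.

### Zero cells

With any zero cell the Wald quantities are undefined. Default behaviour is
to mark the result `undefined` and exclude it from signal lists; the
Haldane–Anscombe +0.5 correction to all four cells is available as an
option. Both paths are logged. No correction is the default because
screened PTs are by construction observed in the target stratum (a ≥ 1)
and large comparator universes rarely have empty cells; the correction
changes small-count RORs materially and should be a conscious choice.

### Normalized frequency

Counts are rescaled as `round_half_up(count / n × 100,000)` reports per
100,000, with n the size of the cohort or stratum the count was taken in
(subgroup screens use the subgroup denominator). Rounding is half-up on the
exact rational — integer arithmetic, no binary-float artefacts — because
published pharmacovigilance tables round halves away from zero, and the
half-up convention is applied consistently to percentages (one decimal for
stratum shares, two for SOC percentages).

### Multiple testing

No multiplicity adjustment is applied across PTs. Screens of hundreds of
PTs at a per-comparison 95% level will flag some PTs by chance; this is the
field's dominant (if criticized) practice for hypothesis *generation*, and
the package documents rather than hides it. Treat flagged PTs as candidates
for review, not findings.

## Cohorts and strata

* **Seriousness** (21 CFR 600.80): a report is serious iff any of the six
  structured outcome flags is set (died, life-threatening, hospitalized,
  prolonged hospitalization, disabled, congenital anomaly). The regulation's
  "medically important" clause requires reading narrative text and is
  deliberately not implemented; an ER visit alone is not serious. This
  narrows seriousness relative to full manual curation and is the
  documented contract.
* **Age groups**: 0–1, 2–10, 11–18, 19–54, ≥55 years with edges [0,2),
  [2,11), [11,19), [19,55), [55,∞), plus "unknown" for missing ages. The
  edges are the only choice consistent with infant cohorts whose observed
  ages run to 1.6 years, child cohorts to 8, adults from 19 to 53 and
  seniors from 55. The 11–18 bin is retained even though pediatric
  pneumococcal cohorts leave it empty — an always-empty bin is an assertion
  the tests can check, not dead code.
* **Onset days**: `NUMDAYS` when present; otherwise `ONSET_DATE −
  VAX_DATE` when both dates parse and the difference is non-negative. When
  both sources exist and disagree, `NUMDAYS` wins with a warning — it is
  the field reporters fill directly.
* **Duplicates**: within one file, first row per report id wins; across
  files (yearly / non-domestic archives), the earliest receive date wins.
  Both are logged. Exact-id matching only; no probabilistic record linkage.

## Time to onset

Onset distributions are summarized by median and quartiles (linear
interpolation between order statistics — the convention is stated because
quartile definitions differ across software) alongside the mean, which in
this data is dominated by a long tail and routinely exceeds the median by
an order of magnitude. Missing onsets are counted, never imputed.
Histograms use integer-day bins 0–30, 31–90, 91–180, 181–360, >360, closed
on both ends (day 30 → first bin, day 31 → second), matching the
conventional interval labels. Cumulative curves are empirical step
functions over non-missing onsets.

## SOC aggregation

The PT → System Organ Class mapping is user-supplied (MedDRA is licensed);
a toy mapping covering every PT the synthetic generator emits ships in
`pvsignal.soc.TOY_PT_SOC` so the pipeline runs end to end offline — it
follows MedDRA naming style but is **not** the licensed hierarchy. The
counting unit is PT occurrences (report × PT pairs), not reports, so SOC
totals exceed the report count; percentages are of mapped occurrences, and
unmapped PTs pool under "Unmapped" with the distinct terms logged.

## The synthetic generator

`pvsignal.synthetic` draws a report population whose latent structure is
known exactly, so parser round-trips, stratum counts and ROR recovery can
be asserted rather than eyeballed. Defaults emulate a pediatric
pneumococcal-vaccine reporting population:

| parameter | default | meaning |
|---|---|---|
| `n_reports` | Synflorix 1,704; PCV7 6,074; PCV13 43,273; PCV15 1,034; PCV20 4,350; PPSV23 49,647; OTHER 50,000 | per-vaccine report totals of the emulated comparison set; OTHER is a generic background standing in for the rest of the reporting universe (the real universe is far larger; 50,000 keeps comparator cells realistic without inflating run time) |
| `p_serious` | 0.49 | serious-report share |
| `death_rates` | per vaccine, 0.5–3.2% | marginal death-report rates; deaths are drawn inside the serious subset so death ⇒ serious by construction |
| `sex_probs` | F .346 / M .400 / U .254 | sex recorded on the report |
| `age_group_probs` | 0–1: 1054/1704, 2–10: 22/1704, 11–18: 0, 19–54: 13/1704, ≥55: 19/1704, unknown: 596/1704 | infant-dominated mixture with a large age-missing share |
| `pts_per_report` | (.15, .20, .25, .20, .20) on 1..5 | PT count per report; mean ≈ 3.1, chosen so occurrence totals resemble real serious-report tables (several PTs per report) |
| onset mixture | π₀ = 0.70 on {0, 1} (78% zeros within), geometric tail mean 31 d | concentrates onsets at 0–1 days and makes the mean (~9–10 d) far exceed the median (0 d) |
| `p_onset_missing` | 0.178 | onset missingness |
| `signal_base_probs` | HHE 5e-4, hypotonia 2e-3, pallor 4e-3, bronchiolitis 5e-4 | background occurrence probabilities of the four signal PTs |
| `true_ror_overrides` | per-vaccine odds multipliers reproducing each vaccine's published per-100k reporting rates for the four signal PTs | the embedded ground truth |

Mechanics: the four signal PTs are independent Bernoulli draws per report
with vaccine-specific probability, applied *before* the PT-count cap, so a
signal PT's marginal occurrence probability is exactly the configured one.
Overrides act on the odds scale (odds_target = multiplier × odds_base) and
are constant across age groups, so when the comparator reports at the base
rate the report-level odds ratio equals the multiplier exactly; the truth
record stores every expected ROR in closed form from the generating
probabilities (pooling the comparator mixture by cohort sizes). Background
PTs fill the remaining 1–5 slots by weighted sampling without replacement
(Gumbel top-k), with age-group-specific weights that skew infants toward
systemic reactions and adults toward injection-site reactions.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real archives: duplicate and near-duplicate
submissions, narrative-only information, co-administration of other
vaccines on one report, secular reporting trends and stimulated-reporting
waves, MedDRA version drift (beyond an optional casing/whitespace noise
toggle), correlations between seriousness and PT profile or onset, and
age-targeted indications (all cohorts share one age mixture). Results on
real data additionally depend on the comparator definition in a way no
synthetic check can validate.

## Problem sizes used in validation

Chosen as the package's own validation design: null CI coverage uses 2,000
replicate 2×2 tables from two 500-report cohorts sharing one PT rate
(coverage must land in 95% ± 2 points); embedded-odds-ratio recovery runs
the full generator 500 times per multiplier ρ ∈ {2, 5, 20} at 2,000
reports per cohort (CI must cover ρ in ≥93% of runs, median ROR within 15%
of ρ); oracle equivalence enumerates all 1,296 tables with cells 1..6
against exact rational arithmetic at 1e-12 relative. End-to-end
determinism is asserted by running the pipeline twice on a seed-1 fixture
and byte-comparing every artifact.

## Known limitations

* Wald intervals undercover for very small cells; screens rank by count,
  so extreme-ROR / tiny-count PTs surface only in the signal flags, where
  `undefined` results are excluded rather than patched.
* Seriousness is flag-only (see above); published serious shares that
  include manual "medically important" upgrades will not reproduce exactly.
* The comparator universe is whatever the supplied files contain; RORs are
  only as meaningful as that universe is representative.
* No PRR, Bayesian shrinkage (IC/EBGM) or multiplicity control — ROR only.
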