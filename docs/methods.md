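# Methods

## Scope and data model

`pvsignal` implements the screening pipeline used for spontaneous
adverse-event report extracts in the style of the FAERS COVID-19 EUA public
dashboard. The unit of analysis is the *report*: one case version carrying
suspected and concomitant products, a list of MedDRA Preferred Terms (PTs),
demographics (sex, age, reporter type, country, event date) and regulatory
seriousness outcomes. The dashboard's export schema is not publicly
documented, so the exchange format here is repository-defined: CSV with
`|`-delimited multi-valued cells, or an equivalent JSON-lines dialect; both
round-trip losslessly and are easy to diff. Dates parse as ISO-8601 only;
anything else becomes missing with a counted warning, so parsing is
deterministic. All label comparisons (products, ingredients, PTs) are
case-insensitive after whitespace normalisation, because dashboard exports
vary in casing. A small PT→SOC table ships with the package as a fixture
standing in for the licensed MedDRA hierarchy; unknown PTs surface as
`UNMAPPED`, never silently dropped.

## Preprocessing

**Deduplication.** Spontaneous databases contain multiple versions of the
same case under different case IDs. Two reports are duplicates when eight
canonicalised fields match exactly: suspected product name(s), suspected
active ingredient(s), reactions, sex, age (rounded to integer years;
missing matches only missing), reporting country, event date, and
concomitant product name(s). Within a collision group the report with the
lexicographically smallest case ID is kept — deterministic and independent
of input order. Identical case IDs with identical keys are treated the same
way. No probabilistic linkage is attempted. Exact eight-field matching can,
rarely, merge two genuinely distinct reports with identical profiles; this
is inherent to the rule, and the synthetic-data tests quantify it (see
below).

**Combination normalisation and multi-drug exclusion.** A drug catalogue
(ten COVID-19 EUA drugs, shipped as `catalog.yaml`) maps ingredient sets of
combination therapies to a single canonical label, with brand synonyms.
Any subset of a report's suspected ingredients exactly matching a
combination's ingredient set collapses to that one label before drugs are
counted, and consumed ingredients cannot re-match single-agent entries
(bamlanivimab inside bamlanivimab/etesevimab counts once). Reports left
with two or more distinct COVID-19 drugs are excluded so each analysed
report attributes its events to at most one drug; reports with none are
retained as comparators.

**Outcome classification.** Outcomes map to exactly one of eight categories
via a configurable precedence order, defaulting to
death > life-threatening > hospitalization > disability > congenital
anomaly > required intervention > other > non-serious; an empty outcome set
is non-serious. The true precedence used in published tables is not
recoverable from their totals (the categories are mutually exclusive either
way), so the most-severe-first convention was chosen and exposed as a
parameter. Classification is a partition: category counts always sum to the
group size, which the tests assert on every generated dataset.

## Disproportionality

For target drug D and PT E the 2×2 table counts *reports*: n11 = reports
with D mentioning E, n12 = reports with D not mentioning E, n21/n22 the
same over all other analysed reports (including reports with no catalogued
drug — the comparator is "everything else in the extract"). A PT listed
twice in one report counts once. The ROR is the cross-product ratio with
the Woolf log-normal interval,

    ln ROR ± z_{1−α/2} · √(1/n11 + 1/n12 + 1/n21 + 1/n22),

z at α = 0.05 being 1.959964 (computed via `scipy.stats.norm.ppf`, not
hard-coded). The interval is unit-tested against an independent sum-of-logs
evaluation and against `statsmodels.Table2x2`. The signal rule is
n11 ≥ 3 AND CI lower limit > 1 (strict); n11 is always the *observed*
co-report count, never a corrected one. The "≥ 3" count rule follows the
standard ROR convention of thresholding the co-occurrence cell. Zero cells
default to the Haldane–Anscombe correction (+0.5 everywhere, `corrected`
flag set); with correction disabled a zero-cell table yields NaN estimates
rather than an exception, so scans never abort. No multiple-testing
adjustment is applied — scan output carries n11 so users can filter — and
no shrinkage estimators (PRR, IC, EBGM) are in scope.

Scans emit one result per PT with n11 ≥ 1, ordered signals-first by
descending ROR, then non-signals by descending n11, ties broken by PT
label, so output is deterministic. Stratified scans (age < 65 vs ≥ 65,
male vs female, healthcare-professional-only) recompute *all four cells*
within the stratum; reports missing the stratifier are dropped from that
stratified analysis only. Empty strata produce empty scans with a warning.

Display rounding is two decimals, half-up (`Decimal`-based), matching
regulatory table style; full precision is kept internally and in TSV
output.

## Synthetic data generator

The generator emulates a dashboard extract with known ground truth. Each
report draws one suspected COVID-19 drug from configured marginals (or
none); each PT is then mentioned independently with probability
`expit(logit(baseline) + log_OR(drug, pt))`, so the true reporting odds
ratio of an injected effect is exactly `exp(log_OR)`. Demographics draw
from categorical marginals with per-field missingness; outcome mixes and
reporter mixes can differ by drug. Two artefact types are injected
deliberately and recorded in a truth ledger: duplicate versions (exact
copies of the eight matching fields under a fresh, lexicographically larger
case ID, so the smallest-ID rule removes precisely the copies) and
multi-drug reports (a second, ingredient-disjoint catalogued drug appended
to an eligible report). A single seeded `numpy` generator drives every
draw; identical configurations produce byte-identical output.

Reports whose independent PT draws all come up empty receive a fixed
padding PT ("Drug ineffective") rather than being redrawn until non-empty:
redrawing would condition every PT indicator on "at least one mention" and
bias the recoverable odds ratios away from the injected truth, whereas
padding leaves the modelled indicators exactly Bernoulli. The padding PT's
own empirical frequency is therefore slightly inflated and no effect is
ever injected on it.

The `preset_paperlike()` configuration reproduces the published extract's
structure: drug marginals follow the published top-ten ranking shares
(target drug ≈ 40%), demographics and outcome mixes follow the published
characteristics table (target drug mostly consumer-reported and 88%
non-serious; other drugs mostly HCP-reported with far more deaths and
hospitalisations), and the disease-recurrence family of PTs carries the
published ROR point estimates as true effects (disease recurrence 212.3 —
back-derived from the published interval, which implies a comparator cell
of ≈ 57 reports in 17,891; symptom recurrence 62.1; therapeutic product
effect incomplete 55.5). Remaining top-event PTs get their published
target-group shares with modest assumed odds ratios (1–12), since their
comparator rates are not published. Duplicate rate 5% and multi-drug rate
0.4% match the published preprocessing waypoints (31,491 → 30,001 → 29,888).

What the generator does **not** model: report-level correlation between PTs
(mentions are conditionally independent given the drug), follow-up version
chains, narrative text, dose fields, reporter-dependent effect sizes, and
fuzzy near-duplicates (injected duplicates match exactly). Passing tests
therefore demonstrate estimator and pipeline correctness under this
idealised law, not robustness to correlated reactions or inexact
duplicates. Chance eight-field collisions between genuinely distinct
reports occur at a rate that grows with the square of the extract size:
negligible at the few-hundred-to-thousand report scale used by the
ledger-exactness tests (verified over 100 seeds), but around one per
10,000+ reports at full scale, which is visible (and harmless) in the
demo pipeline's counters.

## Numerical and design choices

* `sample_fourfold` draws 2×2 tables directly from the generator's marginal
  law for one drug–PT pair (binomial drug margin, then binomial event
  counts in each row). It is the exact marginal of the report-level model
  and is used for Monte-Carlo calibration at scale; report-level
  materialisation adds nothing statistically there.
* Recovery/calibration checks run at n = 20,000 with 500 replicates, drug
  marginal 0.4 and baselines 0.02–0.05, chosen so all expected cells are
  ≥ ~240 and the Woolf interval's asymptotics apply; coverage is asserted
  within 93–97%.
* The per-run problem sizes in the test suite (hundreds to a few thousand
  reports; 200-seed brute-force sweeps capped at 500 reports) keep the full
  suite under half a minute while still exercising every code path; the
  acceptance script runs the paperlike pipeline at the full published scale
  of 29,888 reports.
* Empty strata, empty drug–event subsets and zero denominators produce
  empty tables / NaN with warnings rather than exceptions, so batch runs
  degrade gracefully.

## Known limitations

* The exchange schema is a stand-in, not the dashboard's real export; real
  extracts need a one-off mapping step.
* The PT→SOC fixture covers only the PTs used here; real analyses need
  licensed MedDRA.
* Exact-match deduplication cannot separate true duplicates from identical
  twins, and will not catch near-duplicates with edited fields.
* The comparator group is "all other reports in the extract"; no external
  background population is supported.
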