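# Methods

This note documents the models, operational definitions, parameter defaults
and numerical choices behind `medintel`, and what the synthetic-data tests
do and do not establish about behavior on real hospital exports.

## Resource model and time handling

Only the seven resource types the pipelines consume get typed variants;
everything else is carried as a generic envelope. The original JSON tree is
retained verbatim in every envelope and is the serialization authority, so
round-trips are lossless even for extensions and profile members the typed
layer ignores. Parsing is total by construction: an arbitrary JSON object
produces either an envelope or a structured error naming the offending path
— never an uncontrolled exception. This matters because real exports are
heterogeneous and a pipeline must be able to skip-and-log rather than die
on line 14 million.

Choice-typed temporal fields (`effectiveDateTime` vs `effectivePeriod`,
`performedDateTime` vs `performedPeriod`) normalize to a `(start, end)`
pair with `start == end` for point instants. Timestamps without a UTC
offset are interpreted in a configurable default zone (UTC) and *flagged*
as offset-free rather than silently absorbed: a one-hour misreading would
corrupt every door-to-needle minute. Two renderings of the same instant
compare equal regardless of offset notation. Successful timestamp parses
are memoized; corpora repeat timestamps heavily and the cache is the single
biggest constant-factor win in corpus loading.

Unit handling is deliberately narrow: the UCUM code (or, failing that, the
display unit string) is the comparison key, and the only conversion
implemented is glucose mg/dL ↔ mmol/L (× 18.016), plus `%` for HbA1c —
exactly what the pipelines need. Anything else passes through untouched.

## Search semantics

Queries are conjunctive over one resource type: token filters (with
optional system), date filters, and a subject. Two decisions worth calling
out:

* **Code-prefix matching** implements ICD-10 family semantics: the filter
  `E11` matches `E11.9`. ICD system URIs are matched permissively in cohort
  building because German installations mix `icd-10` and `icd-10-gm` URIs.
* **Interval overlap for dates**: `ge T` keeps resources whose normalized
  *end* is ≥ T and `le T` those whose *start* is ≤ T, so a
  period-valued medication administration spanning a window boundary never
  vanishes from a range query. Point-valued resources degenerate to the
  usual comparisons.

Results are ordered by resource id, making searches, cohorts and reports
deterministic; pagination partitions that order. The indexed search is
property-tested for exact set equality against a test-local full scan that
matches raw JSON directly (no shared predicate code).

## Flattening grammar

The path language is a deliberately minimal tabulation grammar, not a
FHIRPath implementation: dotted member access with collection semantics,
`[i]` indexing of the current collection, `where(system=URI)` coding
filters, and a trailing list mode (`first` default, `join(sep)`,
`explode`). Compilation fails at definition time with a caret-annotated
position; extraction never fails on a missing path — the cell is null and
the row is kept. `explode` on an empty match still emits one row with a
null cell, so patient-level denominators cannot silently shrink; only one
column per extraction may explode. Column types are inferred from the first
non-null value, with a logged fall-back to strings on a clash — predictable
behavior without a schema registry.

## Cohorts

A cohort is the set of patients whose earliest matching condition (by ICD-10
prefix) was recorded in a half-open period `[start, end)`; ties on the
timestamp break by condition id. "Newly diagnosed in the year" is thus
operationalized as *first matching condition recorded in the year* — no
incident-vs-prevalent logic is claimed; an optional look-back exclusion is
available but off by default. Linkage windows may be absolute or relative
to each patient's index date.

## Use-case definitions and parameter defaults

The source summaries these pipelines reproduce do not print their exact
code lists or thresholds, so all of the following are **editorial,
config-surfaced defaults** (shipped in `src/medintel/configs/*.yaml`), not
claims about any particular hospital's rules.

### Myocardial infarction

Denominator: cohort patients (ICD I21 prefix) coded with a STEMI code
(I21.0–I21.3) or carrying a coronary-intervention procedure (OPS 8-837).
Medication categories by ATC prefix: antiplatelet B01AC (single vs dual by
count of distinct agents), statin C10AA, ezetimibe C10AX, anticoagulant
B01AA/AB/AE/AF; the four prefix sets must be pairwise disjoint. Ezetimibe
without a statin stays outside the statin arms of the lipid axis. The
"guideline therapy" flag is a pluggable predicate over the category flags;
the default is *antiplatelet OR statin*. That choice is forced by
arithmetic: it is the only simple rule under which the published margins
decompose consistently (antiplatelet 257 + statin 227 − overlap 223 = 261
treated, complement 98 = the no-antiplatelet/no-lipid cell). The stricter
*(antiplatelet OR anticoagulant) AND statin* reading is available by name
in the config.

### Stroke

Thrombolysis and thrombectomy are identified by procedure codes (OPS
8-020.8, 8-836.80). Admission is the start of the most recent encounter
beginning at or before treatment; if every encounter starts after
treatment, the interval is negative and the patient is flagged as a data
error — counted, but excluded from window statistics. Minutes are floored
(59 min 59 s is 59 minutes). The window boundary is `leq` by default
(treatment at exactly 60/90 min counts as within), with `strict_less`
available; the synthetic generator keeps a 2-minute guard band around the
boundary so classification is never decided by rounding.

Symptom onset is a designated Observation whose *effective time is the
onset instant* (covering both witnessed onset and last-known-well, which
the data cannot distinguish). NIHSS baseline and 24-h values are the
nearest scored Observations within ±12 h of admission and admission+24 h
respectively. ENI classes follow the sign of the 24-h change. Patients
lacking a 24-h NIHSS are excluded with a reason. A designated marker
Observation (e.g. ongoing weaning from ventilation) excludes a patient
from ENI *classification* but not from the onset-time correlation — the
only reading under which the published denominators (101 correlated, 76
classified, 25 excluded) are mutually consistent. The correlation statistic
is Spearman's rank correlation between onset-to-treatment minutes and NIHSS
percent change (baseline 0 is excluded from percent change); the source
figures plot the relationship without naming a statistic, and a rank
statistic is the conservative choice for heavy-tailed timing data.

### Diabetes

The denominator is every patient with ≥1 serum-glucose (LOINC 2345-7,
2339-0) or HbA1c (4548-4) observation in the period — a laboratory screen,
not an ICD cohort. Flags from the per-patient *maximum*: hyperglycemia at
glucose ≥ 140 mg/dL; diabetes at glucose ≥ 200 mg/dL or HbA1c ≥ 6.5 %
(detection source recorded as glucose/HbA1c/both); prediabetes at HbA1c
5.7–6.4 %, optionally extended to the 140–199 mg/dL glucose band (off by
default — in an inpatient population stress hyperglycemia would otherwise
swamp the prediabetes flag). These are ADA-convention cutoffs, configurable
per deployment. Flags deliberately overlap; a separate exclusive severity
takes the worst flag, and dysglycemia is the union. The coding gap compares
the union against any E10–E14/R73 condition in the period. mmol/L values
convert before comparison; non-numeric results are skipped and counted.

### Sepsis

Isolates are culture DiagnosticReports (LOINC 600-7 by default) of cohort
patients (ICD A40/A41) whose conclusion matches an organism lexicon
*exactly* (case- and whitespace-insensitive); unmatched conclusions are
bucketed as `other` and counted. No NLP: deterministic and testable beats
clever here. Antibiotic use is every ATC J01 administration, named through
a configurable ATC→substance catalog. Percentages are over total isolates
and total prescriptions respectively; top-k ordering is count descending,
name ascending — stable under re-runs.

### Prostate cancer

The cohort anchors on C61 diagnoses in the diagnosis year with a two-year
treatment window (PSA surveillance needs the longer horizon). PSA series
are timestamp-ordered and rank-indexed per patient, which normalizes
heterogeneous sampling schedules. Flags, defined only for patients with a
prostatectomy (OPS 5-604) and ≥1 post-operative PSA:

* **Persistence** — first post-op PSA within 180 days ≥ 0.1 ng/mL.
* **Biochemical recurrence** — after any post-op value < 0.1 ng/mL
  (undetectable nadir), a consecutive rising pair whose second value
  ≥ 0.2 ng/mL: a confirmed rise, not a solitary assay blip.

The 0.1/0.2 ng/mL values follow urological convention; all four parameters
are configurable. The flag logic is verified against an independent
brute-force restatement on randomized series.

### Percentages

All printed-style percentages are `100·count/denominator` rounded half-up
to one decimal (`decimal.Decimal`, not banker's rounding), matching how
such results are conventionally reported. Empty denominators yield null,
never a division error.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical structure* the pipelines consume:
a screened population with per-group glycemic value distributions (group
means near 103/112/128/165 mg/dL glucose and 5.2/6.1/7.2 % HbA1c, ~12.5
glucose and ~0.46 HbA1c readings per patient), disease blocks with
configurable prevalences (defaults: MI 2.1 %, stroke 3.6 %, sepsis 5.1 %,
prostate cancer 0.76 % of the screened population, mirroring the relative
cohort sizes of the population it models), treatment-timing mixtures
around the guideline windows, pathogen/antibiotic catalogs with realistic
frequency weights, and post-operative PSA kinetics with a ~5.6 % relapse
rate. Every block draws from its own stream spawned from the master seed
(`numpy` `SeedSequence`), so resizing one block never perturbs another;
resource ids are deterministic; all timestamps carry explicit offsets; all
references resolve by construction.

Generated values keep guard bands around every decision boundary (≥5 mg/dL
around glycemic cutoffs, ≥2 min around timing windows, PSA values off the
0.1/0.2 thresholds), so the planted label is always exactly recoverable
and label *frequencies* are exactly binomial in the configured prevalences
— which is what the parameter-recovery tests assert (exact central 99 %
binomial intervals at n = 10,000).

The count-exact fixture builder is the complement: given a category table
(e.g. 257 of 359 on antiplatelets, 143 of 165 thrombolysed within window)
it constructs a corpus the pipeline maps back to *exactly* those counts.

What passing these tests shows: the pipelines compute their definitions
correctly, deterministically, and at the stated arithmetic. What it does
not show: robustness to the pathologies of real exports — free-text
conclusions outside any lexicon, contradictory duplicate codings, merged
medical records, missing offsets that are *not* UTC, or coding practices
that differ from the shipped prefix lists. Those require site-specific
configuration and validation.

## Problem sizes

The shipped suites use a 600-patient shared corpus (~10,000 resources) for
search/flattening equivalence, 10,000 patients (~160,000 resources) for
prevalence recovery, 500 randomized series/queries for the oracle checks,
and full-scale count tables (35,494 patients for the dysglycemia fixture)
where the reproduced statistic depends on them. These sizes were chosen so
the entire suite exercises every code path at full published scale while
remaining comfortable to run on a laptop.

## Known limitations

* The REST adapter implements the offline search contract over HTTP
  (token/date params, `_count` paging, `next` links) but has no
  authentication and is not exercised against a live server in the suite.
* No FHIR profile/StructureDefinition validation, no XML encoding, no
  chained or `_include` search, R4 only.
* Cohorts do not de-duplicate patients across merged record numbers, and
  episode construction beyond the index condition is out of scope.
* Organism identification is exact-match by design; free-text microbiology
  beyond the lexicon lands in `other`.
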