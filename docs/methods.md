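# Methods

This note documents the model, the synthetic-data generator, the numerical
choices and the known limitations of `screensim`.

## Decision problem and analytic frame

The package evaluates eight study-identification workflows for a weekly
living evidence map as a cost-effectiveness analysis against the manual
baseline (arm 1): conventional Boolean searches of two closed databases,
full manual deduplication and screening, target recall 1.0. The arms vary
five decision axes — search source (conventional "ME" stream vs a single
open bibliographic dataset, "MAG"), two-stage deduplication, a binary
classifier gate, active-learning prioritisation, a fixed weekly screening
target of 1,500 records, and target recall 1.0 vs 0.95. The canonical
eight-arm pattern ships as `data/arms.yaml` and is validated on load; arms
3, 5 and 8 carry the fixed target, arms 4, 5, 7 and 8 the gate, arms 5 and
8 prioritisation.

Perspective is a single payer (one employer funds all staff time); the
horizon is four weeks, so neither costs nor effects are discounted. The
effect unit is an eligible record saved from inappropriate exclusion,
relative to arm 1. Dominance (more effect at less cost) suppresses the
ICER; south-west arms (cheaper, less effective) are reported with a
descriptive cost-saved-per-record-lost ratio rather than an ICER, and
north-east arms get `ICER = ΔC/ΔE`. Points on an axis are assigned to the
non-favourable side (zero effect counts as west, zero cost as south), with
an explicit flag when a zero effect makes the ICER undefined.

## Effectiveness

The gold standard is the union of (i) includes from exhaustively screening
the conventional stream and (ii) eligible records in the top-1,500
score-ranked slice of the open dataset's custom Boolean search stratum,
with duplicate chains resolved to their roots so overlap is counted once.
Recall is measured against this set; precision is includes over records
screen-coded; incremental effectiveness is the include-count difference
versus arm 1.

Count-level replication (`replicate_base_case`) recomputes the per-arm
table from screened/include counts under three analytic assumptions that
the original spreadsheet-style analysis used where direct observation was
unavailable: (i) the fixed-target manual arm inherits the baseline arm's
precision; (ii) the conventionally indexed stratum of open-dataset arms is
included at precision 0.5; (iii) hypothetical extra ineligible records
split between retained and discarded in the observed proportion. Each
assumption activates only where an include count is absent from the
inputs.

## Costing

Hours are linear: `screen_hours_per_100 / 100` per record screened, plus
weekly search and deduplication overheads. Conventional-source arms pay
search and two-stage dedup; open-dataset arms pay only dedup against known
records (their search is automated). Excluded cost heads — search-strategy
development, platform/tooling work, classifier training data, staff
training — are not represented at all. Costs are hours times an hourly
unit cost per currency (GBP and AUD supported); internal arithmetic is
full-precision with half-up rounding to 2 dp only at the reporting
boundary. Cost tables are labelled per evaluation period (four weeks);
any per-week view is a display-time division.

The packaged example inputs decompose the reference per-arm hour totals
as: conventional arms 4 h/week search + 6 h/week dedup, open-dataset arms
2 h/week dedup, with per-arm screening rates (1.80–2.60 h per 100 records)
solved so the totals are reproduced. That decomposition is this package's
own illustrative choice — observed per-arm task-level rates live only in
the original study's data deposit. The GBP hourly rate (30.1295) is backed
out of the baseline arm's published totals; the AUD rate (52.00) is
illustrative. All are config inputs, not constants.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis relies on,
per week of arrival:

| parameter | default | meaning |
|---|---|---|
| `weekly_me_results` | *(required)* | unique conventional records/week; no canonical value exists, so experiments must state it |
| `prevalence_me` | 0.40 | eligibility rate of the conventional stream |
| `weekly_mag_custom` | 1,230 | custom-search records/week (~4,900 per period) |
| `precision_mag_custom` | 0.50 | eligibility rate of the custom stratum |
| `nonenglish_frac_mag_custom` | 0.25 | fully non-English share of that stratum |
| `mag_coverage_of_me` | 0.99 | chance a conventional record is also in the open dataset |
| `mag_only_eligible_frac` | 0.17 | share of gold eligibles reachable only via the open dataset |
| `dup_rate` | 0.10 | injected duplicate share of the weekly conventional yield |
| `score_dist_eligible` | Beta(5, 2) | classifier scores of eligible records |
| `score_dist_ineligible` | Beta(2, 2.5) | classifier scores of ineligible records |

The MAG-only share of eligible custom records is solved in closed form so
the expected MAG-only fraction of the gold standard equals
`mag_only_eligible_frac`. Weekly arrival counts are fixed rather than
Poisson, which keeps runs reproducible and mirrors fixed per-search result
batches; the open dataset's slower release cadence is available as a
one-week availability offset flag rather than a day-level calendar. One
seeded PRNG stream drives the whole corpus; the same seed yields a
bit-identical corpus.

The score distributions are the one genuinely free modelling choice. They
were frozen by Monte-Carlo calibration of an emergent property: a gate
calibrated to 0.95 recall on a 0.40-prevalence stream should discard about
30% of it. Beta(5,2)/Beta(2,2.5) yields 29–32% discard and 0.94–0.95
held-out recall across seeds. Scores are drawn, not computed from text, so
the generator reproduces *rate* structure only: no titles/abstracts, no
citation-graph features, no correlation between a record's language and
its score (the real classifier systematically under-scores non-English
records), and no week-to-week drift in publication mix. Passing tests
therefore demonstrate the machinery and its arithmetic, not performance on
real bibliographic data.

## Workflow engine

Pipeline order is fixed: select source stream → deduplicate (within batch
and against known ids, exact duplicate-chain resolution) → apply the gate →
order → screen week by week → stop. Retention is `score ≥ threshold`;
calibration picks the k-th largest calibration score with
`k = ceil(target · n)`, the largest threshold honouring the target.
Dedup-then-gate order is fixed by construction. Manual (non-prioritised)
screening order is ascending record id — deterministic and
label-independent, standing in for alphabetical order. Prioritised
screening sorts by the effective score
`s_eff = λ·[eligible] + (1−λ)·score0`, `λ = n/(n + halfsat)` with
`halfsat = 2000` by default, re-ranked every 100 screened records (both
configurable). Using the true eligibility flag inside `s_eff` makes the
learner converge to an oracle; it is a deliberately stylised, one-parameter
stand-in for a proprietary active-learning ranker, adequate for comparing
orderings but not for absolute recall-curve claims. The target-recall stop
rule is likewise omniscient — it stops once `ceil(target · eligible_retained)`
includes are found, mirroring a retrospective simulation rather than a
deployable stopping heuristic; with target 1.0 screening continues until
exhaustion.

## Sensitivity analyses

* **Constant time-on-task** replaces every arm's screening rate with the
  unweighted across-arm mean and recomputes costs only.
* **Precision range** re-evaluates the flagship arm (arm 8) at plausible
  precision bounds (defaults 0.55 and 0.72) through the mapping
  `includes(p) = matched_includes + p · sa_screened` with the screened
  denominator held fixed at its sensitivity-analysis input value.
* **Threshold analysis** finds the precision where the flagship arm's ΔE
  crosses zero (dominance flips) by Brent root finding on that same
  mapping, with the tolerance expressed in effect units (default 0.5
  records) and the result reported to 2 dp.

The linear includes(p) mapping cannot simultaneously pass through the
base-case point and reproduce the published lower-bound/threshold pair —
the published figures themselves are not collinear. The packaged
sensitivity inputs (`synthetic_sa_precision.csv`) therefore carry their own
screened denominator (5,791), solved from the lower-bound and threshold
figures; the base-case table is a separate input. This mirrors how the
original analysis kept base-case and sensitivity worksheets distinct.

## Synthetic deposit stand-ins

The original study deposited its count-level worksheets publicly;
`screensim` does not bundle them. Instead, `data/synthetic_base_case.csv`
and `data/synthetic_sa_precision.csv` are *synthetic stand-ins constructed
from the published summary tables*: per-arm screened/include counts chosen
to reproduce the published incremental-effectiveness column, precision
column and gold-standard-consistent recalls. The published table is not
perfectly self-consistent after rounding (the baseline and best-recall arms
imply a gold total near 4,240, while the fixed-target manual arm's recall
implies one near 4,440); the stand-ins bind to the incremental columns, so
two recalls print 0.01 lower than the published rounding (0.54 vs 0.55,
0.78 vs 0.79). Replication runs against the real deposit files — read by
their published names, with a configurable column map because their exact
headers are not hard-coded — remain supported via `--inputs DIR`.

## Monitoring statistic

`cumulative_precision_ci` tracks a deployed workflow's cumulative precision
(total includes over total screened) with a Wilson score interval
(statsmodels implementation). Wilson was chosen over Wald for its behaviour
near 0 and 1, which the early weeks of a deployment visit routinely.

## Problem sizes and numerical choices

Default experiment sizes: 20,000-record streams for gate-calibration
experiments (binomial noise on a 10,000-record held-out half is ±0.5 pp on
the discard share), 50,000+ for law-of-large-numbers checks at 1%
tolerance, 100 seeds × 2,000 records for the prioritisation-vs-random
comparison, and few-hundred-records-per-week corpora for end-to-end
pipeline tests. Ties in every ordering are broken by record id; money is
rounded half-up at 2 dp; degenerate inputs (zero screened, empty gold,
empty score lists, non-bracketing sensitivity ranges) raise typed errors
rather than returning NaNs.

## Known limitations

* No real classifier, no text or graph features; score distributions are an
  assumption, and classifier transferability across sources is not
  modelled.
* Deduplication is exact-key chain resolution; fuzzy-matching errors of
  real dedup tooling (a known practical pain point) are not simulated.
* The active-learning and stop rules are omniscient simplifications (see
  above).
* The effect measure counts records, not downstream review quality; no
  probabilistic sensitivity analysis or acceptability curves are offered,
  matching the deterministic design this package reproduces.
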