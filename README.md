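# screensim

Cost-effectiveness simulation of semi-automated study-identification
workflows for living evidence maps.

## The problem

Teams maintaining a *living map* — a continuously updated, categorised
collection of research records, republished on a weekly cadence — must keep
finding newly published eligible studies. The conventional workflow runs
Boolean searches of multiple closed databases (MEDLINE and Embase), manually
deduplicates the results, and manually screens every unique record. As
publication volume grows, this stops scaling. Candidate remedies are
(a) switching to a single open bibliographic dataset (Microsoft Academic
Graph / OpenAlex) as the sole search source, and (b) adding machine-learning
tools: a binary classifier gate that discards low-scoring records before
human screening, active-learning prioritisation of the screening queue, a
fixed weekly screening target, and a relaxed target recall.

`screensim` simulates the resulting eight workflow arms — every pragmatic
combination of those five decision axes — and evaluates them the way a
health-economic decision model would: each arm is compared with the
baseline manual workflow (arm 1) on **incremental effectiveness** (eligible
records "saved" from inappropriate exclusion, measured against a gold
standard) and **incremental cost** (researcher time-on-task priced at an
hourly unit cost). It is aimed at evidence-synthesis methodologists who
want to stress-test such workflow decisions before changing a production
pipeline.

## The model

For arm *a* with include count *I_a*, screened count *S_a* and gold
standard *G*:

* recall `R_a = |included_a ∩ G| / |G|`
* precision `P_a = I_a / S_a`
* incremental effectiveness `ΔE_a = I_a − I_1`
* hours `H_a = w·(search + dedup) + S_a · r_a / 100` with per-arm screening
  rate `r_a` (hours per 100 records) over `w` weeks
* incremental cost `ΔC_a = c·H_a − c·H_1` at hourly unit cost `c`
* an arm with `ΔE_a > 0` and `ΔC_a < 0` (south-east quadrant of the
  cost-effectiveness plane) **dominates** the baseline and no ICER is
  reported; a north-east arm gets `ICER = ΔC_a / ΔE_a`.

The classifier gate retains records with score ≥ t, where t is the largest
threshold keeping at least the target recall (default 0.95) of a set of
known-eligible calibration scores. Active learning is a stylised
interpolation `s_eff = λ·[eligible] + (1−λ)·score` with
`λ = n_labelled / (n_labelled + halfsat)`, refreshed every 100 screened
records. Deterministic univariate sensitivity analyses hold time-on-task
constant at the across-arm mean, vary the flagship arm's precision between
plausible bounds, and locate (by root finding) the precision at which it
stops dominating the baseline.

A synthetic corpus generator supplies weekly record streams with the
structure the analysis assumes — eligibility prevalence 0.40 in the
conventional stream, a custom-search stratum at precision 0.50 with 25%
fully non-English records, near-complete open-dataset coverage plus a
MAG-only eligible stratum, injected duplicates, and Beta-distributed
classifier scores — so everything is testable without downloading any data.

## Worked example

Recompute the full eight-arm analysis from the packaged deposit-shaped
input tables and print it:

```
screensim replicate --out out/
screensim report out/
```

which prints (abridged):

```
== effectiveness ==
 arm_id  screened  includes  recall  precision  incremental_effectiveness
      1    8800.0      3520  0.8302     0.4000                          0
      2    8350.0      3340  0.7877     0.4000                       -180
      6    8396.0      4198  0.9901     0.5000                        678
      8    4638.0      3989  0.9408     0.8601                        469

== costs ==
 arm_id  hours_total  total_cost  incremental_cost
      1       234.08     7052.72              0.00
      8       128.57     3873.75          -3178.97
```

Reading: the open-dataset arm with gate, prioritisation and a 1,500/week
screening target (arm 8) finds 469 more eligible records than the manual
baseline while costing ≈ £3,179 less over the four-week horizon — it
dominates (south-east quadrant, no ICER). Manual-source automation arms
(2–5) trade recall for cost (south-west). The sensitivity bundle shows the
flip: at precision 0.55 arm 8's ΔE falls to −335 and dominance is lost;
the threshold precision is 0.61. The same pipeline runs on your own
count-level CSVs (`--inputs DIR`), and `screensim simulate --seed N
--weekly-me-results 2000 --out out/` runs the whole stack on a freshly
generated synthetic corpus instead.

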