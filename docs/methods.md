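# Methods

## Counting model

The unit of analysis is the *(report, distinct term)* pair. A
deduplicated report contributes one pair per distinct preferred term it
mentions; at system-organ-class level, one pair per distinct mapped SOC
(two PTs of one report in the same SOC collapse to one pair). The 2×2
margins `a+b` (target) and `c+d` (comparator) are therefore total pair
counts at that level, identical across all terms at the level — in the
reference cohort 1,523 target pairs from 504 reports (≈3 PTs/report)
against 5,188 comparator pairs. The comparator is the rest of the same
indication cohort, not the whole database; both the indication term list
and the date window are configuration.

## Statistics

ROR with the Woolf log-normal CI and PRR with the Pearson chi-square are
computed exactly as printed in the README. Numerical choices:

* `z = 1.96`. With the fuller-precision 1.959964 two upper CI bounds of
  the reference tables round to a different final digit; 1.96 reproduces
  all 54 reference rows (ROR, both CI bounds, PRR, χ²) at printed
  precision, so it is the package default (`pvscreen.Z_95`), overridable
  per call.
* No continuity correction and no zero-cell (Haldane 0.5) correction —
  both validated by exact agreement with the reference values.
* Zero cells make a statistic *undefined*, returned as explicit `None`
  fields (never NaN); an undefined statistic can never satisfy a
  positivity threshold.
* Display rounding is half-away-from-zero (`round_half_away`), matching
  the reference tables; Python's banker's rounding differs on ties.
* Default thresholds are the Evans criteria (`a ≥ 3`, ROR CI low > 1,
  `PRR ≥ 2`, `χ² ≥ 4`). They reproduce the reference flag pattern:
  2 of 24 SOCs positive on both algorithms, 3 more on ROR alone.
* Screen output is ordered SOC block first, then PT block, descending
  `a`, ties alphabetical.

## Deduplication and cohort

Within a `CASEID`, the survivor maximizes `(FDA_DT, PRIMARYID)`
lexicographically; output is in `CASEID` order, so the operation is
order-invariant and idempotent. Drug matching is case-insensitive exact
match after whitespace normalization against a synonym list (generic,
brand, development codes). A report enters the indication cohort if
*any* drug mention carries an indication matching the configured term
list (case-insensitive substring) — indications attach per drug in
FAERS. A report with several matching primary-suspect entries (a data
error) counts once as target and is noted in the log. Ages are
normalized from FAERS unit codes (DEC/YR/MON/WK/DY/HR) to years; values
above 120 years or unparsable become unknown.

## Priority rubric

The printed band edges of the five-dimension rubric overlap
("10–50" vs "<10", "2–5" vs "1–2", "25–50%" vs "<25%"); the
implementation closes them as `[10,50] → 1`, `[2,5] → 1`,
`[0.25,0.5] → 1` with the 2-point band strictly above — consistent with
every reference score. The mortality denominator is target-cohort
reports mentioning the PT. A term on both the IME and DME lists takes
the higher score. Novelty-rule precedence is disease → ambiguous →
label → trial → novel (clinical-irrelevance exclusions dominate);
order is configurable.

## Subgroups

Strata are screened independently with their own margins: sex
female/male (unknown excluded and counted), age `[18, 45]` vs
`(45, ∞)` (age exactly 45 falls in the younger band; under-18 and
unknown excluded). Shared positive PTs are compared by the ratio of
stratum RORs with CI
`exp(ln(ROR_A/ROR_B) ± z·sqrt(V_A + V_B))`, `V` the Woolf log-variance
of each stratum's table. A ratio of reporting fractions would be the
main alternative; the ratio of RORs was chosen because both inputs and
their variances are already produced by the screen.

## Synthetic report generator

`generate_raw_tables` emits DEMO/DRUG/REAC/OUTC in the dollar-delimited
FAERS dialect (header line, no quoting; fields containing `$` are
rejected at generation time since the dialect cannot escape them).
Per report: the primary suspect is the target drug with probability
`target_drug_share` (a random name synonym), else a comparator drug;
the distinct-PT count is zero-truncated Poisson whose *truncated* mean
is `events_per_report_mean` (the underlying rate is solved
numerically); PTs are drawn without replacement — comparator reports
from `baseline_pt_probs`, target reports from the baseline reweighted
by the injected relative reporting ratios and renormalized — using
vectorized exponential sort keys (Efraimidis–Spirakis), which is
exactly sequential weighted sampling. Sex, age band and worst outcome
are categorical draws with explicit unknown masses; about 30% of
reports get a concomitant drug row (occasionally the target drug,
exercising the role filter); with probability `duplicate_rate` a case
is re-filed with version 2, a higher `PRIMARYID` and a later-or-equal
`FDA_DT`. Everything derives from one `numpy` generator seeded from the
config, so identical configs give byte-identical files.

Defaults mirror the reference study conditions: 2,196 cohort reports,
target share 504/2,196, mean 3.0 events/report, the reference sex/age/
outcome mixes (F 43.45% / M 54.96% / unknown 1.59%; <18 0.4%,
18–45 33.33%, >45 40.67%, unknown 25.6%; hospitalization 2.58%, other
IME 6.15%, unknown 91.27%), and `duplicate_rate = 0.05` (the true
re-filing rate of the source database is not published; 5% is a
realistic order of magnitude and exercises deduplication). The
dictionary is the 30 reference PTs plus 30 common background PTs,
uniform baseline by default.

The generator emulates reporting *structure*, not reporting behaviour:
no reporting-delay dynamics, no drug–drug interaction, no country
effects, no PT co-occurrence correlation beyond the shared report.
Passing tests therefore demonstrate correctness of the pipeline's
counting and inference under a known sampling process, not fidelity of
any real database's generative process.

## Simulation studies in the test suite

* **Power**: study-scale config with one background PT given baseline
  per-draw probability 0.004 and relative reporting ratio 5, expected
  target count ≈ 30; the dual-algorithm flag fires in ≥ 95% of 200
  seeded replicates (observed: 200/200, mean a = 30.2).
* **Specificity**: under a global null (1,000 PTs, 20,000 reports,
  uniform baseline, no signal) the per-PT dual-flag rate stayed between
  0.004 and 0.011 across 20 development runs; the recorded acceptance
  bound is 0.02.
* **Fidelity**: with all ratios 1, per-PT target vs comparator
  reporting fractions agree within 3 binomial standard errors at
  n = 50,000; an injected ratio-5 PT (baseline 0.004) shows an
  empirical fraction ratio inside [4, 6]. At higher baseline
  probabilities the observed ratio attenuates below the injected value
  because within-report sampling without replacement makes inclusion
  probabilities sub-linear in the per-draw weights — a known and
  documented property, not a defect.

## Known limitations

* The novelty term lists shipped as defaults are reconstructions from
  the published per-term annotations (label/trial) or illustrative
  (disease-related, ambiguous, IME/DME); real analyses must supply the
  authoritative lists.
* The toy PT→SOC map covers only the bundled dictionary; unmapped PTs
  are counted under an explicit sentinel class rather than dropped.
* Disproportionality on spontaneous reports supports
  hypothesis-generation only: no incidence, no causality, and the
  package deliberately implements no multiple-testing correction or
  Bayesian shrinkage (out of scope).
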