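# pvscreen

Disproportionality-based pharmacovigilance screening for FAERS-style
spontaneous adverse-event report databases, built around the
post-marketing safety assessment of sparsentan (a dual endothelin /
angiotensin II receptor antagonist) in IgA nephropathy.

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) cannot give incidence rates, but they can reveal
drug–event pairs reported *disproportionately* often. `pvscreen`
implements that screen end to end for analysts who want to reproduce or
extend label-era safety profiles:

1. **Ingest** — parse the dollar-delimited quarterly tables (DEMO, DRUG,
   REAC, OUTC), deduplicate cases by the FDA-recommended rules (most
   recent `FDA_DT` per `CASEID`; highest `PRIMARYID` on ties), and select
   the indication cohort, split into target reports (drug of interest as
   primary suspect) and comparator reports (all other primary suspects in
   the same indication).
2. **Screen** — for each MedDRA preferred term (PT) and system organ
   class (SOC), form the 2×2 table of (report, term) pairs

   |                 | term present | term absent |
   |-----------------|--------------|-------------|
   | target drug     | a            | b           |
   | comparator      | c            | d           |

   and compute the reporting odds ratio and proportional reporting ratio

   $$\mathrm{ROR} = \frac{ad}{bc}, \qquad
     \mathrm{CI}_{95\%} = \exp\!\Big(\ln \mathrm{ROR} \pm 1.96\,
     \sqrt{\tfrac1a+\tfrac1b+\tfrac1c+\tfrac1d}\Big)$$

   $$\mathrm{PRR} = \frac{a/(a+b)}{c/(c+d)}, \qquad
     \chi^2 = \frac{N(ad-bc)^2}{(a+b)(c+d)(a+c)(b+d)}$$

   A term is a dual-algorithm signal when `a ≥ 3`, the ROR CI lower bound
   exceeds 1, `PRR ≥ 2` and `χ² ≥ 4` (the Evans criteria).
3. **Novelty** — positive PTs are classified against configurable term
   lists (disease-progression terms, ambiguous-usage terms, drug-label
   adverse events, phase-III-trial adverse events); what survives is a
   *novel* signal.
4. **Priority** — each positive PT is scored 0–2 on five dimensions
   (target-event count, ROR CI lower bound, mortality proportion, EMA
   IME/DME membership, biological plausibility) and the 0–10 total is
   banded weak (0–4) / moderate (5–7) / strong (8–10).
5. **Subgroups** — the screen is re-run within sex and age strata
   (18–45 vs >45) and shared positive PTs are compared by a ratio of
   stratum RORs with a combined-variance Woolf CI.

A **synthetic report-database generator** (`pvscreen.synthetic_faers`)
emulates a FAERS quarter — case/version keys, demographics with explicit
unknowns, drug roles and name synonyms, zero-truncated-Poisson event
counts, duplicate filings — and can inflate chosen drug–event pairs by a
known relative reporting ratio, so the entire pipeline is testable with
a ground truth and no database download.

The package ships the published sparsentan/IgAN screening tables
(FAERS 2023; 24 SOC rows, 30 positive PT rows, priority scores) as plain
CSV reference data used by the golden tests and the defaults.

## Worked example

The hypotension PT row of the reference cohort has a=30, b=1493, c=8,
d=5180:

```python
from pvscreen import ContingencyTable, ror_with_ci, prr_with_chi2, round_half_away

t = ContingencyTable(a=30, b=1493, c=8, d=5180)
ror, lo, hi = ror_with_ci(t)
prr, chi2 = prr_with_chi2(t)
print(f"ROR {round_half_away(ror, 2)} (95% CI {round_half_away(lo, 2)}-{round_half_away(hi, 2)})")
print(f"PRR {round_half_away(prr, 2)} (chi2 {round_half_away(chi2, 2)})")
```

prints

```
ROR 13.01 (95% CI 5.95-28.44)
PRR 12.77 (chi2 68.93)
```

i.e. hypotension is reported for the target drug about 13 times the odds
expected from the comparator background — a dual-algorithm signal
(CI lower bound 5.95 > 1; PRR 12.77 ≥ 2; χ² 68.93 ≥ 4), which the
priority rubric then scores 1 + 2 + 0 + 0 + 2 = 5, a moderate clinical
priority.

End to end on synthetic data, from a shell:

```
$ cat gen.yaml
n_reports: 2196
signal_table:
  - ["Tinnitus", 4.0]
$ pvscreen simulate --config gen.yaml --seed 7 --out q2
$ pvscreen run --config cfg.yaml        # quarter_dirs: [q2], output_dir: out2
...
deduplicated_reports: 2196
target_reports: 490
positive_pts: 1
novel_pts: 1
$ head -2 out2/novel_signals.csv
term,level,status,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,...
Tinnitus,PT,novel,78,1381,86,5084,3.33894,2.44359,4.56234,3.21389,63.9603,...
```

The injected Tinnitus signal is recovered as a novel dual-algorithm
signal; with no `signal_table` the same run yields `positive_pts: 0`.

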