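# pvsignal

Signal detection on FAERS-style spontaneous adverse-event reports:
disproportionality screening with four algorithms applied jointly, plus
Weibull time-to-onset analysis and Table-1-style cohort descriptives.

## Who this is for

Pharmacovigilance analysts and biostatisticians who work with quarterly
extracts of a spontaneous reporting system (DEMO, DRUG, REAC, THER, OUTC,
INDI tables, `$`-delimited ASCII). The package covers the standard
post-marketing workflow for a single target drug: deduplicate report
versions, extract primary-suspect cases, roll MedDRA preferred terms (PT)
up to system organ classes (SOC), screen every term for disproportionate
reporting, and characterise onset timing. A synthetic-data generator emits
FAERS-shaped cohorts with known ground truth (true reporting-rate ratios,
true onset distributions, injected duplicates and malformed dates) so the
whole pipeline is testable without downloading a corpus.

## The statistics

For each drug–event pair, reports are cross-tabulated into a 2×2 table
(a = target drug with the event, b = target drug other events, c = other
drugs with the event, d = the rest; N = a+b+c+d, E = (a+b)(a+c)/N):

| Algorithm | Estimate | Signal criterion |
|---|---|---|
| ROR  | (a·d)/(b·c), 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | lower bound > 1, a ≥ 3 |
| PRR  | [a/(a+b)] / [c/(c+d)] with Pearson χ² | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
| IC   | log₂((a+0.5)/(E+0.5)); IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) | IC025 > 0 |
| EBGM | a·N/((a+b)(a+c)); EBGM05 = exp(ln EBGM − 1.645·√(1/a+1/b+1/c+1/d)) | EBGM05 > 2 |

A term is a **signal** only when all four criteria hold simultaneously. A
full empirical-Bayes gamma-Poisson shrinker (two-component gamma mixture
prior fitted by maximum marginal likelihood) is available as the rigorous
EBGM variant (`--ebgm mgps`).

Time-to-onset (event date − earliest complete therapy start date, whole
days) is summarised by median/IQR, monthly bins and a cumulative curve,
and fitted with a two-parameter Weibull. The shape β classifies the hazard
over time: CI entirely below 1 → *early failure* (risk concentrated soon
after starting therapy), above 1 → *wear-out*, spanning 1 → *random*.

## Worked example

```bash
pvsignal simulate --out data --n-cases 5000 --seed 42
# wrote 5000 cases (500 target) to data

pvsignal screen --input data --drug rucaparib --drug rubraca --level pt --out pt.csv
# 2 signals in 2 SOCs (29 terms scored)
```

Two of the screened rows from `pt.csv`:

```
level,soc,term,a,ror,ror_lo95,ror_hi95,prr,chi2,ic,ic025,ebgm,ebgm05,...,signal,corrected
pt,Nervous system disorders,Dysgeusia,24,4.69,2.81,7.81,4.56,42.48,1.63,0.95,3.24,2.11,...,True,False
pt,Skin and subcutaneous tissue disorders,Photosensitivity reaction,32,17.39,9.37,32.29,16.60,150.96,2.47,1.88,5.98,3.56,...,True,False
```

Dysgeusia was reported by 24 target-drug cases; its reporting odds ratio
is 4.69 (95% CI 2.81–7.81), its IC lower credibility bound 0.95 > 0 and
its EBGM05 2.11 > 2, so it meets all four criteria — both flagged terms
are planted effects of the generator (true rate ratios 12 and 15; the
measured ratios sit below truth because elevated terms also inflate the
target profile denominator — see `docs/methods.md`).

```bash
pvsignal tto --input data --drug rucaparib --drug rubraca
# all: n=437 median=4.0 IQR=(0.0, 38.0) alpha=21.14 beta=0.38 (0.36-0.41) early
# Gastrointestinal disorders: n=145 median=2.0 IQR=(0.0, 30.0) alpha=17.45 beta=0.36 (0.32-0.40) early
# ...
```

Across 437 cases with a complete, non-reversed date pair, half of events
occurred within 4 days of starting therapy, and the Weibull shape 0.38
(95% CI 0.36–0.41, entirely below 1) marks an early-failure hazard —
exactly the onset profile the generator simulates. `pvsignal run` executes
the whole pipeline (screen at both levels, TTO per SOC, cohort summary,
stage-by-stage run log) from a YAML config.

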