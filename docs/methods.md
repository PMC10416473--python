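# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports in the FAERS
quarterly-extract layout: six `$`-delimited ASCII tables (DEMO, DRUG,
REAC, THER, OUTC, INDI) keyed by report version (PRIMARYID) and case
(CASEID), a deleted-case list, and a user-supplied PT→SOC dictionary
(3-column TSV: `pt`, `soc`, `is_primary`) standing in for the licensed
MedDRA hierarchy. All identifiers are read as text; nothing is coerced to
numbers silently.

Cleaning follows the standard recipe: for each CASEID keep the row with
the numerically highest PRIMARYID (exact ties keep the first row in file
order — the rule only speaks of *lower* version numbers), then drop cases
on the deleted list. Target-drug cases are those with at least one DRUG
row in the requested role (primary suspect by default) whose `drugname`
or `prod_ai` contains a synonym, case-insensitively after trimming;
verbatim FAERS drug names carry brands, salts and free text, so substring
matching is the default and exact matching a flag. Ages are harmonised to
years (DEC×10, MON÷12, WK÷52.143, DY÷365.25); unknown codes map to
missing or `unknown`, never dropped.

The counting unit everywhere is the unique (case, term) pair at the
analysis level, so duplicate REAC rows never inflate counts; a case
reporting a PT twice counts once, and a case reporting two PTs of one SOC
counts once at SOC level. Raw event-row counting is available by skipping
the dedup of pairs, but unique-case is the default and the tested path.

## Disproportionality screen

Each term's 2×2 table (rows: target drug / other drugs; columns: term /
other terms; margins a,b,c,d, N, E=(a+b)(a+c)/N) feeds four algorithms:

- **ROR** = ad/bc, CI = exp(ln ROR ± 1.96·se), se = √(1/a+1/b+1/c+1/d).
- **PRR** = [a/(a+b)]/[c/(c+d)] with the Pearson χ² of the table. No
  Yates continuity correction by default (flag available); published χ²
  values at screen scale are far too large for the correction to matter.
- **IC** = log₂((a+0.5)/(E+0.5)). The +0.5 offsets are the Bayesian
  shrinkage that keeps the statistic finite at a=0. The lower credibility
  bound uses the two-term expansion
  IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2), which depends on the
  data only through a — so a printed (a, IC) pair is enough to recompute
  it, which is exactly what `scripts/acceptance.py` does.
- **EBGM** defaults to the closed-form relative reporting ratio
  a·N/((a+b)(a+c)) with a log-normal 90% lower bound (EBGM05,
  z = 1.645). The full MGPS shrinker is the opt-in rigorous mode: λ (the
  true relative reporting rate) gets a two-component gamma mixture prior
  whose five hyperparameters maximise the negative-binomial mixture
  marginal likelihood of the observed counts across all tables at one
  level (Nelder–Mead on log/logit-transformed parameters, conventional
  start (0.2, 0.1, 2, 4, 1/3)); the posterior is again a gamma mixture,
  EBGM = exp(E[ln λ]) via digamma, EBGM05 the posterior 5th percentile by
  bracketed root finding on the mixture CDF.

The normal quantiles are the conventional rounded 1.96 and 1.645, as the
formulas are written in practice.

**Joint rule.** A term is a signal only when all four criteria hold at
once: ROR lower bound > 1 with a ≥ min_count (default 3); PRR ≥ 2 with
χ² ≥ 4 and a ≥ min_count; IC025 > 0; EBGM05 > 2. No multiple-testing
adjustment is applied — the conjunction of four criteria is the
(deliberately conservative) guard, and on simulated null cohorts of 200+
terms the realised false-signal fraction is far below 5%.

**Zero cells.** The Haldane–Anscombe +0.5 correction (all four cells) is
applied only when a zero cell makes ROR/PRR/EBGM undefined, and the row
is flagged `corrected`; IC needs no correction by construction. Outside
the screen, scalar functions raise a `ZeroCellError` unless the caller
opts in.

Report output rounds half-up to 2 decimals; library functions return full
precision.

## Time-to-onset and the Weibull shape-parameter test

TTO = event date − earliest day-precision therapy start date, in whole
days; 0 means same-day onset and is retained. Only complete YYYYMMDD
dates qualify; partial (YYYY/YYYYMM), missing/invalid, and reversed
(event before start) cases are excluded and counted per reason, with the
precedence missing → partial → reversed when several apply (the
conservation identity candidates = included + three exclusion counts
holds under any ordering). A case contributes its onset to every SOC it
reports, so per-SOC sample sizes overlap and sum past the all-group n.

Summaries use linear interpolation between order statistics for
median/quartiles (IQR endpoints depend on this convention), 30-day bins
with a >360-day overflow, and the empirical cumulative curve.

The two-parameter Weibull is fitted by maximum likelihood: the shape
solves the profile score equation Σtᵝln t/Σtᵝ − 1/β − mean(ln t) = 0 by
bracketed root finding (values normalised by their maximum to avoid
overflow at large shapes), the scale follows in closed form. 95% CIs are
Wald intervals on (ln α, ln β) from the observed information (central
finite differences of the log-likelihood), exponentiated — mirroring what
commercial statistics packages report. Zero-day onsets are mapped to 0.5
days *inside the fit only* (the density needs t > 0); the raw sample is
untouched elsewhere, and the mapping is configurable. Fits require n ≥ 10
and non-constant data; degenerate inputs raise a descriptive error
instead of returning garbage. Failure type: β CI entirely below 1 →
early, above 1 → wear-out, spanning 1 → random.

Note on day resolution: on integer-day data with β ≈ 0.3 the rounding
plus the 0→0.5 mapping concentrates mass at half a day and biases β̂
upward by roughly 0.05–0.10. The parameter-recovery tests therefore
simulate continuous onset times (the fit's own sampling model); fits on
day-resolution pipeline output should be read with that bias in mind.

## Cohort descriptives

The Table-1 generator reports, per block, the *available-n* (cases with
the item recorded) and percentages on that denominator: sex, age bands
(<18, 18–65, >65), weight bands (<80, 80–100, >100 kg), US/non-US,
indications and comorbidities (indications of the primary-suspect drug
vs. indications attached to co-reported drugs), top-k combination drugs
(non-PS rows, once per case per ingredient, k=5 default), outcome
seriousness with subtype multiplicity (a case hospitalised and later dead
counts in both subtypes; subtype percentages are on the serious-case
count), reporter type, reporting year, and medians with IQR for age and
weight. Exhaustive blocks sum to 100% ± rounding. A zero denominator
yields an explicit `None`, never a silent 0.

## Synthetic cohorts and what they do (not) show

The generator emulates the statistical structure the pipeline assumes:
per case, one primary-suspect drug (the target with probability
`target_drug_share`, otherwise a background drug), independent Bernoulli
draws per catalog PT with probability baseline (background) or
min(baseline·RR_true, 1) (target), Poisson-many concomitant drugs (role
C) with occasional comorbidity indications, ~39% serious cases with
multiplicity-bearing outcome codes, therapy starts spread over
2017–2022, and one event date per case: start + a rounded Weibull draw
for its first reported term (PT-specific parameters, falling back to the
term's SOC, then to scale 16.57 d / shape 0.28 — an early-failure onset
profile). Same-day events arise naturally from rounding. Data defects are
injected at configurable rates with exact self-auditing counts:
duplicate report versions (second DEMO row, higher PRIMARYID), deleted
cases, right-truncated partial start dates, reversed date pairs. A case
whose Bernoulli draws all miss receives one baseline-weighted fallback
PT, so every case carries a reaction; the fallback draw is always
consumed, keeping the random stream — and hence the emitted bytes —
deterministic in (config, seed).

Two structural properties of profile-based disproportionality show up
clearly in synthetic cohorts and are worth understanding before reading
any screen:

1. **Profile dilution.** When several terms are elevated at once, target
   cases carry more terms overall, inflating the target profile
   denominator; every measured ratio then sits below its RR_true. The
   default effect map keeps total excess reporting mass moderate for this
   reason.
2. **Margin contamination.** E and the (a+c) margin include the target
   drug's own reports, so when the target contributes a non-trivial share
   of all report pairs, RRR/EBGM and IC are pulled toward 1 even for a
   single elevated term. This vanishes at realistic drug shares (a real
   corpus has any one drug at well under 1% of reports) — which is why
   the recovery validation uses cohorts of 80,000 cases at a 1% target
   share (expected a ≈ 100–120 per planted term, ~3.7 PTs per case), 20
   replicates, recovering planted rate ratios of 2, 5 and 10 within
   −20%…0% (geometric mean) for all four estimators.

The generator does **not** simulate reporting dynamics over calendar
quarters, drug–drug interaction structure, dose fields, synonym noise in
background drug names, or correlated PT co-reporting. Passing tests
therefore demonstrate the pipeline's arithmetic and filtering contracts
under known truth — not that real-corpus signals are causal, nor that
FAERS biases (under-reporting, stimulated reporting, indication
confounding) are handled; disproportionality cannot estimate incidence,
as the denominators are unknown.

## Numerical and validation choices

- Validation sizes: null false-signal control on one 8,000-case cohort
  with 200 null PTs; planted-effect recovery on 20×80,000-case cohorts;
  Weibull recovery across shapes {0.3, 1, 2.5} × scales {10, 50} with 20
  fits of n=1,000 each (CI coverage ≥85% observed; classification correct
  in ≥18/20 for the unambiguous shapes); closed forms checked against
  exact-rational/reordered-float oracles on 1,000 random tables at 1e-10
  relative, and against statsmodels/scipy cross-implementations.
- MGPS caveat: fitted on data that is truly null, the mixture prior
  degenerates to a spike at λ=1 (the correct ML solution); shrinkage
  behaviour should be assessed with priors fitted on heterogeneous data.
- `pipeline.run_pipeline` logs the case count at every stage (read →
  dedup → extract → map → screen → TTO) and writes deterministic CSVs;
  timestamps live only in the log.
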