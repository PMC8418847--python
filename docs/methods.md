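# Methods

This note documents the model, the estimation and simulation machinery,
the numerical choices, and the limits of what the test suite demonstrates.

## Cohort model

Three health states — progression-free (PF), progressive disease (PD),
death — with death absorbing and no PD→PF recovery.  The cycle length is
2 months (6 cycles/year); the cohort starts fully progression-free at age
50, the mean trial age at diagnosis.  The engine is a plain
row-stochastic matrix iteration; conservation of cohort mass holds to
1e-12 per cycle and is property-tested, and the deterministic trace is
cross-checked against an independent 100,000-patient microsimulation of
the same chain (agreement within 3 Monte-Carlo standard errors).

**Row normalization.**  The published PF rows sum to 0.999 rather than 1.
Two repair policies are provided: `proportional` (default) rescales every
entry by the row sum; `residual_to_death` leaves non-death entries
untouched and assigns the shortfall to death.  The conclusion is
insensitive to the choice (tested).

**Lifetime horizon.**  "Lifetime" is operationalized as the first cycle at
which the surviving fraction drops below 1e-4, capped at age 100 (300
cycles).  With the base-case matrices the cap binds (300 cycles); both
arms are always compared over a common horizon.

**Bevacizumab arm (secondary data).**  Only the chemotherapy matrix is
published for the systematic-review source, alongside pooled risk ratios
for progression-free (0.72) and overall survival (0.84).  The default
transform treats the ratio as acting on the per-cycle hazard,
p′ = 1 − (1 − p)^RR — the standard probability↔rate conversion, which maps
[0,1] into [0,1] for any positive RR and is identity at RR = 1.  RR(PFS)
adjusts PF→PD; RR(OS) adjusts PF→death and PD→death; diagonals absorb the
change.  A `direct` mode (p′ = RR·p) is retained for calibration
experiments; it can leave the unit interval for RR > 1 and then raises.

**Background mortality.**  No other-cause mortality table is published;
none is applied by default.  A per-cycle background hazard hook exists and
combines with disease-specific death as independent competing risks.

## Valuation

Costs are per-cycle, per-state, per-arm amounts in IDR, split into direct
medical, direct non-medical and indirect components; the healthcare
perspective counts only the first, the societal perspective all three.
Utilities are arm-specific EQ-5D-5L index values as published — the
bevacizumab arm's are *lower* (0.793/0.659 vs 0.864/0.724), which is
counterintuitive but deliberately not "corrected".  Death carries zero
cost and zero utility; no terminal-care cost is applied (none is given).

Accrual uses beginning-of-cycle occupancy for cycles 0..N−1; an optional
half-cycle correction averages adjacent boundaries (off by default, as
spreadsheet-origin models typically omit it).  Both cost and outcome
streams discount at 3%/year, compounded fractionally per cycle,
(1+r)^(−k/6); a legacy per-cycle mode exists for calibration exploration.
All arithmetic is in IDR; USD is a reporting-time conversion at 14,250
IDR/USD, back-derived from the published anchor "57 million IDR = USD
4,000", and always configurable.  The ICER is reported only in trade-off
quadrants; dominance labels otherwise; the cost-effective flag is
NMB ≥ 0 at the WTP threshold (3 × GDP per capita = $10,800/QALY).

## Probabilistic sensitivity analysis

The source table names no distribution families; the assignment follows
standard practice and is overridable:

| input | family | parameterization |
|---|---|---|
| transitions with printed α/β | Beta | α, β verbatim |
| other transitions | fixed | point value |
| utilities | Beta | method of moments (mean, SE) |
| costs | Gamma | method of moments |
| risk ratios | log-normal | method of moments |

The printed α/β pairs are numerically inconsistent with their own point
estimates (e.g. a PD→death of 0.026 printed with α = 3, β = 13, whose mean
is 0.19).  They are used verbatim, as published; no reconciliation is
attempted.  Consequently the PSA explores a parameter region shifted away
from the deterministic base case, and reproduction of the published CEAC
is approximate: with 1,000 draws the curve reaches ~52% acceptance at a
WTP of 250 million IDR (the publication reports 40–60% there) but ~59%
at 300 million (reported: near 100%).

Non-medical and indirect cost components have SE equal to their mean,
which the moment fit maps to Gamma with shape 1 (exponential) — genuinely
high-uncertainty inputs.

Parameters are drawn independently (no correlation information exists),
in sorted name order from one seeded generator, so the entire draw table
is reproducible from (spec set, n, seed).  After a draw, sampled entries
keep their values and the remaining entries of each row are rescaled
proportionally into the residual mass 1 − Σ(sampled) — the standard
complement parameterization; a row whose sampled entries already exceed 1
rejects the draw (impossible under the default families, counted and
logged if user-supplied specs allow it).  When a block has no sampled
entry, the base-case matrix is reproduced exactly, so a fully degenerate
spec set collapses the CEAC to a step function at the deterministic ICER
(tested).  The default WTP grid spans 0–1,000 million IDR in 10-million
steps, covering the 250/300-million region of interest.

## Estimation from patient records

Records are irregular per-visit observations.  Discretization assigns to
cycle k the last observed alive state before the end of the cycle's
interval (LOCF); a death at month m is recorded at the boundary of the
cycle containing it, ⌈m/2⌉, with alive states carried forward up to the
preceding cycle; censoring truncates the sequence.  Data observed exactly
at cycle boundaries lose no transitions (tested).

Transition probabilities are event fractions over at-risk cycles, with a
uniform Beta(1,1) prior added to the event/non-event counts so that the
resulting α, β are always valid PSA inputs; raw counts are available via
`prior=(0,0)`.  Strictly consecutive cycles only are counted; an
observation gap breaks the chain.  Fewer than 75 at-risk records in a
state triggers a warning (the study's minimum-sample guidance), not an
error.  Kaplan–Meier median survival uses the product-limit estimator
(lifelines) with "not reached" reported when the curve never crosses 0.5.
Cost components and utilities are summarized as means with standard
errors of the mean over contributing rows; a single contributing patient
yields a mean with the SE flagged unavailable.  EQ-5D-5L values are
consumed as pre-scored indices; tariff computation is out of scope.

## Synthetic cohorts

The generator emulates the retrospective four-hospital cohort: state
paths simulated from per-arm true matrices (defaults: the real-world
blocks), gamma-distributed billing amounts and beta-distributed utility
indices per alive cycle (the same families the PSA uses), and independent
uniform censoring.  Defaults: 43 chemotherapy + 96 bevacizumab patients
(the study's arm sizes), 36 cycles (6 years) of follow-up — comfortably
covering the survival scale observed in the records — and a 20% censoring
fraction, a typical loss level for retrospective multi-hospital reviews
(the publication describes no censoring mechanism).  What the generator
does *not* emulate: hospital-level clustering, informative censoring,
visit-time irregularity (observations fall on cycle boundaries), or
correlation between costs and disease severity within a state.  Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to real-world messiness.

## Validation experiments (sizes and design)

* Trace conservation: 1,000 random valid chains, 40 cycles each.
* Microsimulation oracle: 100,000 patients, 60 cycles, both arms.
* Estimator recovery: 20 replicate cohorts of 2,000 patients/arm; the
  mean estimate over replicates must sit within ±0.02 of every generating
  probability (observed bias is < 0.001; the bound is dominated by the
  ±3σ of the replicate mean).
* End-to-end (generate → estimate → model): the ICER is a ratio of two
  small differences and is hypersensitive to the PD→death hazards — at
  2,000 patients/arm a *single* cohort's ICER has a sampling SD of ~25%,
  so no per-cohort bound is meaningful.  The experiment therefore follows
  the field convention of computing the ICER from the *mean* increments
  (ΔC̄, ΔQ̄) over 10 replicate cohorts, generated with follow-up to
  absorption (240 cycles) so the estimators observe the full disease
  course; the generating truth is the secondary parameter set, whose
  ICER is well-conditioned.  Measured pooled error is 2–4% against the
  10% bound.  The real-world parameter set is unusable as generating
  truth for this purpose: its incremental cost (−12M IDR) is smaller than
  cost-sampling noise and the comparison quadrant flips between
  replicates.

## Known limitations and open inconsistencies

* The published per-arm QALY totals (1.90/2.07) are not derivable from
  the published inputs under any calibration documented here; this
  package's base case yields 3.78/4.13 QALYs and an ICER of $32,984/QALY
  — the same side of the $10,800 threshold and the same conclusion, but
  not the same internals.  The text ICER of 653 million IDR also differs
  from the ratio of its own printed components (108/0.17 = 635 million).
* The real-world transition probabilities imply multi-year survival,
  inconsistent with the published real-world medians (8.8/12.5 months),
  and give the bevacizumab arm a *higher* progressive-state death hazard;
  run as printed they make bevacizumab less effective.  Both quantities
  are reported; no forcing of agreement.
* First-line therapy only: no second-line states, no tunnel states, no
  time-varying probabilities, no subgroup analyses, no budget impact.
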