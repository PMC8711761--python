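# Methods

`renalcea` is an individual-patient (microsimulation) cost-effectiveness
model of first-line nivolumab+cabozantinib versus sunitinib for advanced
renal cell carcinoma (aRCC) from a US payer perspective, with a fixed
downstream sequence — axitinib (second line), sorafenib (third line), best
supportive care (BSC) — ending in death. This note records the model, its
assumptions, the numerical choices, and what the synthetic-data fixtures do
and do not emulate.

## State structure and cycle mechanics

Patients are simulated one 42-day cycle at a time (42/30.4375 ≈ 1.3799
months, 42/365.25 ≈ 0.1150 years) from model entry at age 62 until death or
an age cap of 100 years (≈330 cycles); an explicit shorter horizon can be
set for scenario analyses. The state is the pair (treatment line, time on
line). Within a cycle, events resolve in a fixed priority order with at most
one transition per cycle:

1. **Death.** Background mortality from an age-indexed life table
   (annual probability rescaled to the cycle under a constant hazard,
   `1 − (1−q)^(Δ/12)`), plus a one-time adverse-event (AE) mortality
   probability in the first cycle on a line, plus — in BSC only — disease
   death driven by the BSC overall-survival (OS) law. Competing sources
   combine multiplicatively on survival probabilities.
2. **Progression.** The per-cycle progression probability at time-on-line
   `t` is the standard discretisation `tp(t) = 1 − S(t+Δ)/S(t)` of the
   line's progression-free-survival (PFS) law.
3. **AE discontinuation.** The published cumulative discontinuation
   probability for a line is spread over that line's fitted median PFS as a
   constant per-cycle hazard, `1 − (1−P)^(Δ/median)`; charging it in a
   single cycle would distort time on treatment.

Progression or discontinuation advances the line index; disease mortality
before BSC is carried implicitly by progression through the sequence into
BSC, whose OS law (derived from a previously treated aRCC population)
governs death there. This is the model's single largest structural
assumption — see Limitations.

## Survival laws

Each line's PFS (and the BSC OS) is a parametric law with time in months:
log-logistic `S(t) = 1/(1+(t/scale)^shape)` for both first-line regimens,
axitinib and the BSC OS, and exponential for sorafenib. In this
log-logistic form the median equals the scale, which is how the
parameterisation was validated: the fitted sunitinib scale (8.269) matches
the trial's printed 8.3-month median PFS. The sorafenib exponential is
parameterised by its **mean** survival time (2.281 months); the source
table is ambiguous between mean and rate, and the rate reading (median 0.3
months) is clinically implausible, but both are selectable in the
configuration (`parameterization: mean|rate`).

The `survival` module also fits all five standard families (exponential,
Weibull, lognormal, gamma, log-logistic) to right-censored individual
patient data by maximum likelihood — bounded quasi-Newton on
log-parameters, three starting points, censored-data log-likelihood — and
ranks them by AIC (`2k − 2ℓ`, ties broken by parsimony then a fixed family
order). This supports re-deriving inputs from curve data rather than taking
the shipped parameters on faith.

## Curve reconstruction (pseudo-IPD)

`km_reconstruct` inverts a digitized Kaplan-Meier figure plus its
numbers-at-risk table into pseudo individual patient data, following the
standard iterative interval scheme: censoring is assumed uniform within
each risk-table interval, the interval's censor count is adjusted until the
implied number at risk at the next interval boundary matches the published
one, and event counts at each digitized click follow the product-limit
ratios. Implementation details that matter:

* censor times are spread over the interval's click span and binned to the
  click whose step contains them, so a censor assigned to a click is still
  at risk at that click;
* the final interval (no terminal risk count) starts from the prior
  intervals' observed censor rate and, when a total event count is
  published, is iteratively adjusted until the totals agree; any residual
  after integer rounding is resolved by relabelling the *earliest* records
  (where risk sets are largest, so the curve moves least);
* event allocation never consumes the entire risk set while the digitized
  curve is still positive;
* non-monotone digitized points are repaired by isotonic clipping (with a
  warning), duplicate times collapse to the lower survival value.

The product-limit estimator used to validate reconstructions is implemented
directly and cross-checked against lifelines at 1e-10 in the tests.

## Costs, utilities, discounting

All costs are 2021 USD. Drug acquisition is priced per cycle from unit
prices and dosing schedules: nivolumab 240 mg every two weeks (3 doses per
cycle, each with one ≤1-hour IV administration fee), cabozantinib 40 mg
daily, sunitinib 50 mg daily for 28 of 42 days, axitinib 5 mg twice daily,
sorafenib 400 mg twice daily. Oral drugs are priced dose-proportionally
against their unit strength; this only matters for cabozantinib (40 mg
daily at a 60 mg unit price, i.e. ⅔ × $491.30/day). The flat
price-per-day reading was rejected because it is arithmetically
incompatible with the published analysis it mirrors: first-line acquisition
alone would exceed the published arm total. AE-management costs are charged
once at line entry; BSC costs $1,256 per cycle; patient weight is retained
as a hook but no listed drug is weight-banded.

Utility is accrued per cycle (0.82 / 0.77 / 0.66 / 0.494 by line), with a
one-cycle disutility of 0.157 at line entry weighted by the line's
grade-≥3 AE probability (75.3% and 70.6% for the two first-line regimens;
0.50 and 0.45 for axitinib and sorafenib, configurable — they are not
printed in the mirrored table and contribute <0.01 QALY). Costs and
utilities accrue for every cycle the patient begins alive and are
discounted at 3%/year with the discrete factor `(1+r)^(−t)` at cycle end;
a half-cycle toggle exists but is off by default, matching the mirrored
analysis's silence on the point.

Both arms share one pre-drawn set of uniform streams (common random
numbers), so incremental outcomes are free of between-arm sampling noise
and a price change in one arm leaves the other arm bit-identical.
`expected_outcomes` computes the exact expectation of the engine by
occupancy bookkeeping over (line, time-on-line); the stochastic engine is
tested to converge to it.

## Background mortality fixture

The bundled life table is Gompertz:
`q(x) = 1 − exp(−(B/ln c)·c^x·(c−1))` with defaults `c = 1.094`,
`B = 4.0266e−5`, calibrated so remaining life expectancy at 62 is ≈21
years, matching a recent US all-population table at the model's entry age.
Any exact table can be substituted from CSV (age, annual death
probability); ages beyond the table use the terminal row.

## Uncertainty program

* **One-way (tornado):** each parameter moves to its bounds with all else
  at base under common random numbers; costs use ±20%, utilities and the
  AE disutility use their printed ranges, weight 49–93.8 kg, starting age
  18–75 (the source discusses lowering age to 18 but prints no upper
  bound; 75 is the configurable default).
* **PSA:** gamma for costs, beta for probabilities and utilities, normal
  for starting age and weight (clipped to their ranges), hyperparameters
  moment-matched from the mean and either a printed SD (second/third-line
  utilities) or the range treated as a 95% interval (SD = range/3.92).
  Probabilities with no printed range use the ±20% convention. Infeasible
  beta SDs are clipped with a warning. Survival shape/scale parameters are
  structural and stay fixed. The full profile is 5,000 iterations × 2,000
  patients; the documented reduced profile (200 × 500) is what the test
  suite and the reproduction script run.
* **Scenarios:** drug (or whole-strategy) price fractions, truncated
  horizons (5/10/15 years), and arm-specific direct-to-BSC switching after
  first-line progression (18.9% / 32.9%).

## Synthetic digitization fixture

`synth_km_digitization` emulates a digitized published figure: simulate
`n` subjects from a known law under *independent* uniform censoring
`C ~ U(0, c_max)` — `c_max` solved by quadrature so the expected censored
fraction hits the requested rate — compute the Kaplan-Meier curve, and
click it at equally spaced survival levels (dense where the curve moves,
as a human digitizer clicks) with a uniform-interval risk table. It does
not emulate digitization coordinate jitter, informative censoring, or
risk-table transcription errors; round-trip tests therefore show that the
reconstruction inverts clean digitizations, not that it repairs corrupted
ones.

## Numerical choices

* Median survival: closed forms where they exist; gamma by root-finding to
  |S−½| < 1e−10.
* MLE: L-BFGS-B on log-parameters, three starts, `ftol` 1e-12; degenerate
  inputs (<2 events) are rejected.
* Transition grids: where a law's survival support is numerically
  exhausted (S(t) = 0 at an unreachable state) the transition is taken as
  certain rather than raising.
* Problem sizes: base case and scenarios run 20,000 patients per arm
  (≈1-2 s each, vectorised over patients); the convergence oracles use
  50,000; the PSA reduced profile is 200 × 500.

## Limitations

* The mirrored analysis combined per-line trial mortality ("observed
  mortality rate" from each trial's survival data) into its death
  probabilities. Those per-line OS curves are not part of this model's
  input table, so here death before BSC arises only from background and
  AE mortality. The consequence, measured against the published results:
  incremental cost reproduces closely (within ~3%) and every published
  ordering (price fractions, horizons, BSC switching, cost-saving sign of
  the whole-strategy-25% scenario) holds, but absolute per-arm costs and
  the ICER run high (~+35%) and the incremental QALY low (~−24%), because
  second/third-line and BSC exposure is not trimmed by in-treatment
  disease death. Starting age, a major driver in the mirrored analysis,
  is a minor one here for the same reason.
* Heavy log-logistic tails are extrapolations; the lifetime horizon caps
  them at age 100 but they still dominate BSC duration.
* No dose reductions, treatment interruptions, vial wastage, or
  weight-banded pricing; no societal perspective; two-strategy frontier
  only.
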