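# Methods

## Analysis model

The outcome is antibiotic treatment of an RTI episode; the exposure is the
pandemic period. With a single binary exposure the log-binomial regression
MLE coincides with the ratio of observed treated proportions, so risk ratios
are computed in closed form:

    RR = (x1/n1) / (x0/n0)
    95% CI = exp(log RR ± z * sqrt((1 - p1)/x1 + (1 - p0)/x0)),  z = 1.96

where subscripts 0/1 denote the pre-pandemic and pandemic periods. The Wald
CI on the log scale is standard for ratios of proportions and is verified in
the test suite against an iteratively fitted log-binomial GLM (statsmodels)
to |Δlog RR| < 1e-8. We use z = 1.96 rather than the exact normal quantile;
the difference is invisible at the two decimals reported. A zero treated
count leaves the RR undefined and raises an error rather than applying a
silent continuity correction.

Analyses are stratified separately by age group (ten bands: 0–4 … 85+),
service type × consultation count, and consultation mode × count; service
and mode are crossed with count because a mixed episode necessarily has two
or more consultations. Heterogeneity of stratum RRs is tested against the
Mantel–Haenszel pooled RR with the inverse-variance-weighted statistic

    Q = Σ_i (log RR_i − log RR_MH)² / se_i²,   Q ~ χ²(k−1) under homogeneity.

The precise Mantel–Haenszel heterogeneity variant is a design choice (several
exist); this Q-statistic is documented here and exercised by a type-I-error
simulation. Antibiotic-type distributions across years are compared with the
Pearson chi-squared test of independence (scipy, no continuity correction).

## Episode and treatment definitions

- **Chain rule.** "Within 30 days" is read inclusively: a gap of exactly 30
  days chains, 31 starts a new episode. Same-day repeat consultations remain
  separate consultations in one episode. The builder is tested for exact
  equality with a brute-force transitive-chaining oracle (connected
  components of the ≤30-day link graph) and for input-order independence.
- **Linkage window.** Both endpoints inclusive (lag 0 and lag 7 link): the
  week-long window absorbs pharmacy closures. A dispensing is attributed to
  its nearest preceding consultation (same-day ties to the earlier-entered
  claim), once, regardless of episode boundaries; the episode-level treated
  flag is unaffected by attribution, only type tables are.
- **Mode derivation.** A claim is electronic iff every recognised procedure
  code on it is electronic-type; claims mixing in-person and electronic codes
  classify as in-person (in-person billing dominates such claims); claims
  with no recognised procedure code are rejected by default (configurable to
  assume in-person).
- **Periods.** Pre-pandemic 2018-03-12 – 2019-11-30 and pandemic
  2020-03-12 – 2021-11-30, equal length by construction; episodes are
  assigned by index date, so an episode extending past a window end stays in
  its index's period. January 2018 and December 2021 are trimmed before
  episode building on the comparative path only, because episode and
  linkage definitions look across day boundaries; the monthly-rate path
  keeps all months.
- **Age** is completed years at the index consultation — an episode-level
  attribute must be fixed per episode, and the index date is the natural
  reference.
- **COVID-specific episodes.** Two exclusion modes exist for the non-COVID
  sensitivity analysis: drop episodes containing *any* COVID-specific
  diagnosis (default) or only episodes whose *every* RTI diagnosis is
  COVID-specific; the mode is recorded in output metadata.

## Denominators

Monthly population counts are first-of-month snapshots: a person counts in a
month iff alive and resident on its first day (a mid-month death still counts
that month; a mid-month birth counts from the next). A snapshot is
reproducible and standard; mid- or end-of-month alternatives differ
negligibly at population scale. An optional frozen-cohort mode excludes
persons entering after a cutoff, mirroring registries whose final study year
lacks updates for newborns and migrants. Yearly rates per 1000 use the mean
of the twelve monthly snapshots as the denominator. Person-time denominators
and age-standardisation are out of scope.

## Synthetic registry generator

The generator emulates the data-generating structure the analysis assumes,
not Norwegian demography in detail:

- **Consultation process.** Index consultations follow an inhomogeneous
  Poisson process with daily rate
  `baseline/30.4375 × (1 + A·cos(2π(doy − peak)/365.25)) × m(t)`, where
  `m(t)` is the spike multiplier (default 2.5) for 30 days from the pandemic
  start, the suppression multiplier (default 0.75) thereafter, and 1 before.
  A single cosine is the simplest shape producing the observed winter peak.
  Baseline 0.019 consultations/person-month was calibrated once to the
  published ballpark of ≈220–245 episodes/1000 inhabitants/year.
- **Follow-ups** occur with probability 0.25, uniform 1–30 days after their
  parent, chaining geometrically with no depth cap (mirroring the analysis,
  which caps neither episode length nor consultation count).
- **Treatment.** Propensity attaches to the index consultation (0.26 before
  the pandemic start, 0.135 after — true RR 0.519); this is the simplest
  mechanism making episode-level treated fractions match the configured
  propensities. Dispensing lags default to P(0)=0.55, P(1)=0.2, P(2)=0.1,
  P(3)=0.05, P(5)=0.05, P(10)=0.05, deliberately placing 5% of true
  treatments beyond the 7-day window to exercise the linkage boundary
  (period-independent leakage cancels in the RR). Unrelated urinary-agent
  dispensings are added at 0.05 per person-year as linkage noise.
- **Modes and codes.** Electronic-consultation probability switches from
  0.005 to 0.40 at the pandemic start; 12% of consultations are out-of-hours;
  15% of pandemic consultations carry a COVID-specific code (half of those
  exclusively). Diagnosis codes use a default ICPC-2
  respiratory-infection list (R72–R83, H71, COVID codes R991/R992) that is
  explicitly an editable configuration, not an asserted registry standard.
- **Determinism.** Every stage derives its own generator from the scenario
  seed, so identical configurations yield byte-identical tables and any
  stage can be regenerated independently.

What the generator does *not* emulate: realistic age-specific consultation
and prescribing gradients (rates are age-uniform), migration, multi-drug
regimens, epidemic dynamics, or regional structure. Passing recovery tests
therefore show that the pipeline estimates the treatment-propensity ratio
without bias under the assumed structure — not that it is robust to
real-world confounding the generator does not produce.

## Validation strategy and problem sizes

- Published stratified aggregates (episode counts and treated percentages per
  stratum and period) are reconstructed by `round(N × %/100)` (half away from
  zero — the inverse of how the percentages were printed) and pushed through
  the estimator; the resulting RRs reproduce the published values at two
  decimals. CI bounds may shift by one final-digit unit since the
  reconstruction inherits the 1-decimal rounding of the printed percentages.
- Episode building is checked against the chaining oracle on 1000 random
  patients with up to 200 consultations each.
- Parameter recovery runs 100 seeded replicates at 20 000 persons; the 95%
  CI covers the true RR in ≥90 of them (observed ≈95, consistent with
  nominal coverage).
- The heterogeneity test's type-I error is estimated from 10 000 simulations
  of 3 homogeneous strata at n = 5000 per stratum per period (p₀ = 0.25,
  common RR 0.6); the stratum size is chosen for validity of the asymptotic
  χ² reference.

## Numerical conventions

Report rounding is half-away-from-zero: RR and CI to 2 decimals, percentages
to 1. Column percentages are rounded per cell (matching the printed-table
convention), so a column of k cells can drift from 100.0 by up to k × 0.05.
Empty strata are emitted with blank statistics rather than dropped; empty
report windows yield zero counts with blank percentages. Dates are whole
calendar days throughout (all definitions are day-granular).

## Known limitations

- The RTI and COVID ICPC-2 code lists and the consultation procedure codes
  are editable defaults; real extracts require confirming them.
- One demographic row per person with a single residency interval
  (denominators only use residency; multi-interval histories would not touch
  any reported quantity).
- Treatment is inferred from dispensing within a time window, which can
  misattribute unrelated antibiotics to an RTI episode; period-stable
  misattribution does not bias the period comparison.
- Unadjusted, separately stratified RRs only; no covariate-adjusted or
  interrupted-time-series modelling, and no multiple-testing correction.
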