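# Methods

## The model

`aquarisk` estimates non-carcinogenic health risk from drinking
contaminated groundwater. The chronic daily intake of chemical *i*
through drinking water is

    Exp_i = C_i · I_w / BW        [mg/kg/day]

where `C_i` is the concentration in water (mg/L), `I_w` the daily water
intake (L/day) and `BW` the body weight (kg). Uncertainty and
population variability are propagated by Monte Carlo simulation: each
iteration draws the triple (C, I_w, BW) independently and combines it.
Risk is characterised per chemical by the hazard quotient

    HQ_i = Exp_i / RfD_i

against the USEPA chronic oral reference dose, with HQ > 1 flagging
intake above the level considered safe for lifelong exposure, and by
exceedance probabilities — the fraction of trials strictly above a
threshold dose. Carcinogenic slope-factor risk and hazard-index
summation across chemicals are deliberately out of scope, as are
exposure routes other than drinking water (diet, soil/dust ingestion,
dermal contact).

## Distributions and their parameterization

* **Concentrations** are lognormal. When only a summary table is
  available (the usual case for the packaged Gaza data), the spec is
  moment-matched to the arithmetic mean m and SD s:
  `sigma² = ln(1 + s²/m²)`, `mu = ln m − sigma²/2`. This reproduces the
  mean and SD exactly but not necessarily the sample median — for
  nitrate (mean 112, SD 74 mg/L) the implied median is 93.4 mg/L,
  matching the observed 93; for near-symmetric parameters such as
  fluoride (mean = median = 1.1 mg/L) the matched lognormal's median
  falls ~10 % below the sample median, which propagates into slightly
  lighter upper exposure tails than a raw-data fit would give. This is
  the main residual discrepancy of summary-level reproduction.
  Well-level data can instead be fit with `fit_lognormal` (log-space
  sample moments after censor substitution; censored-likelihood/Tobit
  fitting is not implemented).
* **Body weights** are lognormal, parameterized from a (median, P95)
  pair: `mu = ln median`, `sigma = ln(p95/median)/z_0.95`. Built-in
  groups: adult male 80/100 kg, adult female 65/85 kg, children 1–3
  years 12.5/20 kg.
* **Water intake** is uniform over the quoted range — adults
  Uniform(0.5, 2) L/day, children Uniform(0.25, 1) L/day. The source
  quotes only the range; uniform is the minimal assumption, and a
  triangular spec is available where a modal intake is defensible.

Single-well point-source anomalies (PO4 at 72 mg/L, Cu at 18 μg/L) are
modelled as a point mass at the detected value, i.e. a degenerate
lognormal with sigma = 0. A network-wide exposure distribution for a
contaminant seen in one well is not meaningfully estimable from that
one value; the point mass makes the assumption explicit rather than
hiding it in a fit.

## Monte Carlo details

Default 100,000 iterations, default seed 2022 (the campaign year);
both are config-overridable, and every simulation is bit-reproducible
for a fixed seed because the draw order (C, then I_w, then BW) is
fixed. Empirical percentiles use linear interpolation between order
statistics (`numpy.percentile`, method `"linear"` — the convention of
the spreadsheet-style risk simulators this workflow descends from);
the estimator is selectable. At n = 100,000 the median's Monte Carlo
noise is ≪ 1 % relative, negligible against the ±20 % reproduction
tolerances used in the tests.

Cross-population contrasts (e.g. child vs adult-male median intake) run
both scenarios on the same seed. Because both intake distributions are
affine maps of the same underlying uniform stream and both body-weight
distributions are exponentials of the same normal stream, matched seeds
cancel sampling noise almost exactly and the contrast isolates the
scenario parameters. HQ tables derive each parameter's seed from (run
seed, parameter index), shared across scenario blocks, for the same
reason.

Hazard-quotient percentiles are exposure percentiles divided by the
RfD — exact, since division by a positive constant is monotone and the
quantile estimator is positively homogeneous; the test suite asserts
this identity rather than trusting it. Exceedance uses strict `>`
(ties count as non-exceeding) and carries a binomial standard error
√(p(1−p)/n).

## Censoring

Six trace metals (Al, As, Cd, Co, Ni, Pb) are below the instrumental
detection limit in every well. Summary statistics substitute LOD/2 for
censored values by default (common environmental practice; full-LOD and
zero substitution are selectable), and parameters censored in *all*
wells are flagged and excluded from exposure assessment entirely —
simulating exposure from a detection limit would manufacture risk from
absence of signal.

## Guideline screening

Screening compares the campaign mean against the WHO guideline value
with strict inequality (a mean exactly at the guideline passes).
Parameters without a guideline (pH's range-form guideline, HCO3, Sr,
PO4) return an explicit `not_screenable` status. Two reference-table
quirks are preserved deliberately: the Mn guideline is stored as
printed in the source summary (0.8 on a μg/L row, inconsistent in
magnitude with WHO practice) with a runtime warning, and the Ag RfD is
taken as the standard USEPA 5.0×10⁻³ mg/kg/day because the source
table's exponent is internally inconsistent — both overridable in the
run config. Alternate health benchmarks (WHO/EFSA nitrate ADI
3.7 mg/kg/day, EFSA fluoride adequate intake 0.05 mg/kg/day) are
reported alongside the USEPA values, never silently substituted.

## The synthetic well network

The well-level observations behind the packaged summary table are not
openly deposited, so the generator manufactures a 115-well campaign
with the structure the analysis assumes: five governorates with
30/34/18/22/11 wells (quota-limited round robin by well index),
independent lognormal marginals moment-matched per parameter,
all-censored metals emitted at their detection limits, and
single-detection point sources. Detection limits for PO4
(0.01 mg/L) and Cu (0.1 μg/L) are synthetic stand-ins (typical
ion-chromatography / ICP-MS limits); the published table prints none.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: spatial gradients (the real network
shows strong south–north salinity and fluoride structure),
inter-parameter correlation (Cl–Na–TDS co-vary under seawater
intrusion), temporal pairing between campaigns, and non-lognormal
shapes (bromide's sample mean 3.54 vs median 0.25 mg/L implies a far
heavier tail than its matched lognormal). Clipping draws to the
observed [min, max] is available but off by default, since clipping
shifts the matched moments; moment-recovery tests run unclipped.

## Numerical choices and degenerate inputs

* Lognormal constructors reject non-positive means; `sd = 0` and
  all-identical fit inputs yield an explicitly flagged degenerate
  (point-mass) spec rather than an error.
* `lognormal_from_median_p95` requires p95 > median (zero spread is not
  identifiable from two equal quantiles).
* `fit_lognormal` uses ddof=1 for the log-SD, so tiny hand-checkable
  fixtures reproduce the textbook sample SD.
* Round-trip identities (moment matching, median/P95) hold to 1e-10 and
  1e-6 relative respectively and are tested at those tolerances.
* Percent change between campaigns requires a strictly positive
  baseline mean.
* Pipeline outputs embed a config hash, seed and iteration count in
  '#'-comment headers; a rerun with an identical config is
  byte-identical. Stage failures remove partial outputs and name the
  failing stage.

## Problem sizes

The shipped analysis is desk-scale by construction: 29 parameters, 17
of them exposure-eligible, 3 scenarios, 100,000 iterations — the full
pipeline runs in a few seconds on one CPU. Structural tests use
500–20,000 iterations; distributional and acceptance checks use the
full 100,000.

## Known limitations

Independence of C, I_w and BW is assumed (and surely wrong in detail —
intake scales with body weight); concentrations are pooled across the
whole network rather than stratified by governorate; no
censored-likelihood fitting; no goodness-of-fit testing of the
lognormal assumption; RfD uncertainty is not propagated. The published
adult-female "+18.7 %" relative-exposure figure is not reproducible
from the stated scenario parameters — the median body-weight ratio
80/65 gives +23 %, which is what `relative_exposure` computes and
reports; the package does not force the published number.
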