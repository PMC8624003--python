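# Methods

## Decision-tree cohort model

A closed cohort of `cohort_size` patients (default 10,000) with elevated
cardiovascular risk is initiated on statin therapy and followed for one
month (most SAMS cases arise within weeks of initiation, so a 1-month
horizon captures the events the test can influence). Two strategies are
compared:

- **no testing** — every patient starts simvastatin;
- **testing** — *SLCO1B1* C-allele carriers (`p_carrier`, default 0.256,
  the projected prevalence in the target health system) are switched
  before initiation, a fraction `switch_to_atorva` (default 0.5) to
  atorvastatin and the rest to rosuvastatin; non-carriers start
  simvastatin.

Assumptions, stated openly:

- Myalgia and myopathy are **independent per-patient risks**; a patient
  can contribute to both expected counts. Genotype-attributable risk is
  **additive** (`p_base + p_gen`) and applies only to carriers who remain
  on simvastatin; the alternative statins are modelled as carrying no
  genotype-attributable risk.
- Discontinuation is **event-conditional** and applied to expected event
  counts, not to patients: expected discontinuations =
  `0.27 × myalgias + 0.40 × myopathies`. A patient with both events can
  therefore contribute two discontinuation events; at the default event
  rates the distinction is numerically negligible (≈0.01 events in
  10,000 patients).
- Statin costs accrue for the full month regardless of discontinuation
  (timing within the month is unspecified; this is the simplest
  contract).
- Perfect uptake: every carrier flagged by the test is switched. The
  model is therefore a best-case bound on benefit.
- Counts are reported with a **floor** display rule. Floor (not
  round-half-up) is required to reproduce both published discontinuation
  counts simultaneously (109.2 → 109 and 78.57 → 78); internal
  arithmetic stays fractional.

## Calibration of the default inputs

The original model's appendix inputs are not public, so the defaults are
**back-calculated reconstructions** from the published cohort outputs,
and are labelled as such wherever they appear. Overriding them with true
values via the YAML config changes nothing structurally.

Event probabilities (1-month, probability scale):

| parameter | default | derivation |
|---|---|---|
| `p_carrier` | 0.256 | projected carrier prevalence |
| `p_myalgia_gen` | 109/2560 ≈ 0.04258 | averted myalgias ÷ carriers |
| `p_myopathy_gen` | 3/2560 ≈ 0.00117 | averted myopathies ÷ carriers |
| `p_myalgia_base` | 291/10000 = 0.0291 | non-genetic myalgias ÷ cohort |
| `p_myopathy_base` | 0 | forced by the discontinuation arithmetic |
| `p_disc_myalgia` | 0.27 | published event-conditional rate |
| `p_disc_myopathy` | 0.40 | published event-conditional rate |

`p_myopathy_base = 0` is the unique choice consistent with the floor
arithmetic of both discontinuation counts; whether the original model
used exactly zero or a negligible value cannot be determined from the
published outputs.

Unit costs (2020 USD): the test costs 99 USD. The remaining five unit
costs are under-determined by the two published per-patient totals
(28 USD without testing, 124 USD with), so the package fixes two ratios
a priori — statin monthly prices in the proportion
simvastatin : atorvastatin : rosuvastatin = 1 : 3 : 8, and myopathy
management at 5× myalgia management — and solves the simvastatin price
and the myalgia cost from the two identities (`solve_unit_costs`). The
solved values are ≈3.70 / 11.10 / 29.59 USD per month and ≈585.57 /
2927.85 USD per event; both per-patient totals are then reproduced
exactly, and the solved set is emitted in the provenance JSON. (Fixing
the three statin prices at *absolute* 1/3/8 USD instead leaves no
non-negative solution for the event costs; the ratio formulation is the
package's resolution of that under-determination.)

## Probabilistic sensitivity analysis

Default distributions (`with_default_distributions`): **beta** on the
four event probabilities, parameterized by method of moments from the
point estimate with SD = 25% of the point (the published hyperparameters
are not available; the 25% spread mirrors the ±25% used for cost
variation); **triangular** `(0.75·point, point, 1.25·point)` on carrier
prevalence, discontinuation probabilities and all unit costs. The 50/50
switch split and the cohort size are structural and never sampled.
Parameters at zero stay fixed.

One `numpy.random.Generator` stream drives a run; draws are consumed in
sorted parameter-name order, so adding a tracked output can never
perturb the draws, and runs are bitwise reproducible per seed.
Probability draws outside [0, 1] (possible only for user-supplied
triangulars) are rejected and redrawn, never clamped; the pair
constraints `p_*_base + p_*_gen ≤ 1` are enforced the same way.
Summaries report min, max, mean and nearest-rank 2.5th/97.5th
percentiles side by side (the published ranges are min/max; the
percentile flavour is a free choice and nearest-rank is the documented
one). Iterations with zero events averted have no meaningful cost per
event averted; they are recorded as undefined, excluded from that
output's summary only, and counted.

Note that with these reconstructed distribution widths the PSA ranges
are wider than the published ones; the published point estimates are
bracketed, which is what the test suite asserts.

## Microsimulation oracle

`simulate_cohort` draws carrier status binomially, the carrier switch
per patient, and event/discontinuation indicators per patient, using a
single uniform per event type so that a realised event is attributed to
the genetic cause with the correct conditional probability. Its
aggregate discontinuation count sums cause indicators (matching the
expected-count convention above); the per-patient table keeps a single
`discontinued` boolean. Replicate-averaged aggregates agree with the
expected-value engine within Monte Carlo error — the test suite checks
3 standard errors over 200 replicates on three parameter sets, with the
full cohort size (10,000) for the calibrated defaults and 2,000 for the
stress sets (smaller cohorts keep the check inexpensive without
weakening it, since the standard errors scale accordingly).

## Synthetic trial generator

Emulates a pragmatic provider-clustered trial of PGx result delivery:

- **Clusters:** 39 providers; cluster sizes `1 + NegBin(r=0.7, mean 10)`
  truncated to [1, 61], giving median 7 and ≈409 expected patients —
  matching the published provider count, median and range. Truncation is
  by redraw.
- **Randomization:** patient-level Bernoulli within provider
  (probability 193/408 of PGx+). The real design was a two-level
  pseudo-cluster procedure; simple stratified assignment preserves the
  feature that matters for the analysis — both arms present within a
  provider.
- **Cascade:** offer (33.7%/32.1% by arm) → prescription (13.5%/11.2%
  marginal; the conditional probability is derived) → statin type
  (pooled mix 76/18/6 atorva/simva/rosuva) → SAMS (7.7%/12.5% of users)
  and discontinuation (11.5%/16.7% of users).
- **Costs:** per category and arm, zero-inflated gamma with the zero
  mass configured per category (large for inpatient and SAMS care, small
  for primary care and laboratory) and the gamma moments solved so the
  *marginal* mean/SD equal the published per-arm values. Feasibility
  requires `1 − p_zero > m²/(s²+m²)`; infeasible configurations raise.
  Statin costs attach only to actual prescriptions. The PGx test cost is
  structural: 99 USD iff PGx+.
- **Utilization counts:** moment-matched negative binomial (Poisson when
  the variance does not exceed the mean).

What it deliberately does **not** emulate: within-patient correlation
between cost categories (categories are independent given arm, so
generated *total*-cost SDs are smaller than the published ones, ≈32k vs
38k for PGx+ — the published totals are kept in the config for
reference); provider-level outcome effects (clusters are pure sampling
units); visit-level timing and diagnosis-code streams; and a strict tie
between the SAMS flag and SAMS-care costs (the published SAMS-care
moments — mean 3, SD 27 — are unattainable under strict gating at the
≈1% SAMS marginal prevalence, so SAMS-care is its own zero-inflated
category with `p_zero = 0.985`). Passing tests therefore validate the
analysis machinery on data with realistic margins and clustering, not
the correlation structure of real administrative cost data.

## Cluster bootstrap

Providers are resampled **with replacement, jointly across arms**,
preserving the provider count; the between-arm difference of
patient-level means is recomputed per replicate and the 95% interval is
the 2.5th/97.5th percentile of the replicate distribution. Design
choices: joint (not per-arm) resampling matches clustering at the
provider level under pseudo-cluster randomization; **percentile** (not
BCa) intervals are the simplest defensible flavour given that the
published analysis cites generic cluster-bootstrap references.
Replicates in which one arm receives no patients are redrawn and
counted, with a hard failure after 100 redraw rounds. Binary outcomes
are reported in percentage points, costs in USD; the sign convention is
PGx+ minus PGx−. Percentile intervals need not contain the point
estimate in pathological resamples; this is flagged on the estimate,
not raised.

Calibration: on null synthetic data (both arms drawn from the same
generator) with a well-behaved outcome and 1000 replicates per CI, the
measured coverage of nominal 95% intervals is ≈94% over 2000 simulated
trials. This sits slightly below nominal — expected for percentile
intervals on ~40 clusters with heavy size imbalance — and degrades by
roughly another point on heavily skewed, zero-inflated outcomes at the
published cost scales. Users needing exact nominal coverage on such
outcomes should increase the cluster count or consider studentized
intervals; this is a known limitation.

## Cost ladders and scenarios

Cost tiers are nested supersets, from the intervention-immediate set
(PGx test + lipid therapy + SAMS care, with a statin-only variant) out
through cardiology, primary care, laboratory/imaging (the full
"directly attributable" set) to total costs. Scenario analyses rescale
the PGx test cost column (×0, ×0.75, ×1.25), statin costs (×0.5, ×2.0),
or filter to subgroups (statin users, TC/CC carriers, TT, high
ASCVD-risk patients), recomputing derived columns before re-running the
ladder; the immediate-tier point delta responds exactly linearly to the
PGx cost factor because every PGx+ patient carries the same 99 USD test
cost. GEE-adjusted differences are deliberately out of scope; a
cross-check hook (`gee_difference`) wraps statsmodels for comparing
point estimates only.

## Numerical conventions

- Probabilities live on [0, 1]; percentages appear only in reports.
- Currency adjustment is a pure CPI ratio with user-supplied index
  values; no CPI table is bundled.
- The carrier switch under testing is deterministic at cohort level in
  the expected-value engine (odd expected counts put the extra patient
  on atorvastatin) and stochastic per patient in the microsimulation.
- Empty cohorts, empty subgroup filters, unknown strategies/outcomes and
  invalid distributions raise typed errors (`ConfigError`,
  `ValidationError`) naming the offending key.
- All randomness flows through explicit `numpy.random.Generator` seeds;
  every CLI run writes a manifest with seeds and a digest of the
  resolved parameters.
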