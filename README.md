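# pgxcca

Cost–consequence analysis of preemptive *SLCO1B1* pharmacogenetic (PGx)
testing for statin myopathy risk.

The *SLCO1B1* rs4149056 C allele impairs hepatic statin transport and
raises the risk of statin-associated muscle symptoms (SAMS — myalgia and
myopathy), most strongly for simvastatin. Testing patients *before* statin
initiation lets prescribers steer carriers to an alternative statin
(atorvastatin or rosuvastatin) and avoid genotype-attributable muscle
events — at the price of the test. This package quantifies that trade-off
for health-economics and pharmacogenomics researchers in two complementary
ways:

1. **A 1-month decision-tree cohort model** of a closed cohort of 10,000
   patients initiated on simvastatin, comparing a *testing* strategy
   (carriers switched 50/50 to atorvastatin/rosuvastatin before
   initiation) with *no testing* (everyone stays on simvastatin),
   evaluated as expected values, with:
   - a **probabilistic sensitivity analysis** (PSA): beta distributions on
     the 1-month myalgia/myopathy probabilities, triangular (±25%)
     distributions on all other inputs, Monte Carlo propagation;
   - an **individual-level microsimulation** that draws every patient's
     genotype, assignment, events and discontinuation as Bernoulli
     indicators — the brute-force oracle for the expected-value engine.
2. **A trial-alongside cost–consequence analyzer** for patient-level
   records from a provider-clustered pragmatic trial of PGx result
   delivery (PGx+ = results released immediately, PGx− = usual care):
   per-arm summaries, between-arm mean differences with **percentile
   cluster-bootstrap 95% CIs** (providers resampled with replacement, all
   their patients travelling together), nested **cost-category ladders**
   (from intervention-immediate costs out to total costs), and
   scenario/sensitivity analyses (test cost ±25% and zero, statin costs
   50–200%, clinical subgroups). Because real trial records are
   access-restricted, a **synthetic trial generator** emulates the cohort
   structure: two arms nested in 39 provider clusters (median cluster
   size 7, range 1–61), 29.4% carrier prevalence, the statin
   offer → prescription → type cascade, and right-skewed per-category
   costs drawn from moment-matched zero-inflated gamma distributions.

## The model in brief

For strategy *s*, cohort size *N* and carrier prevalence *p_c*, expected
1-month event counts are

    myalgia(s)  = N·p_mya_base + C_simva(s)·p_mya_gen
    myopathy(s) = N·p_myo_base + C_simva(s)·p_myo_gen

where `C_simva(s)` is the number of carriers still on simvastatin
(`N·p_c` without testing, 0 with testing). Discontinuations apply
event-conditional probabilities (0.27 after myalgia, 0.40 after
myopathy) to the expected counts. Strategy cost sums the test (99 USD per
patient, testing arm only), one month of statin therapy by assignment,
and per-event management costs. Printed counts use a floor display rule;
internal arithmetic stays fractional.

The default event probabilities and unit costs are **calibrated
reconstructions** (the original model's appendix inputs are not public):
they are back-calculated so the best-case run reproduces the published
cohort outputs, and are clearly labelled as such — see
`docs/methods.md`. Any of them can be overridden with a YAML config.

## Worked example

```sh
pgxcca best-case --out out/bc
```

writes `events.csv`, `costs.csv` and `comparison.json`:

```json
{
  "averted_myalgia": 109,
  "averted_myopathy": 3,
  "discontinuations_testing": 78,
  "discontinuations_no_testing": 109,
  "incremental_cost_per_patient_usd": 96.0,
  "cost_per_event_averted_usd": 8571.42857142857
}
```

Reading: among 10,000 patients initiated on statins, 2,560 carriers are
switched off simvastatin before initiation; this averts 109 myalgias and
3 myopathies (112 of 403 total muscle events without testing, 27.8%),
cuts expected discontinuations from 109 to 78, but costs 96 USD more per
patient (124 vs 28 USD), i.e. about 8,571 USD per muscle event averted.

```sh
pgxcca psa --iterations 1000 --seed 1 --out out/psa
```

propagates the default input distributions; with this seed the summary
reports 212–695 total no-testing muscle events (mean 402.8, bracketing
the 403 point estimate), 41–224 events averted, and 3,402–28,146 USD per
event averted.

The same machinery is callable as a library:

```python
from pgxcca import default_parameters, run_comparison
testing, no_testing, cmp = run_comparison(default_parameters())
cmp.averted_myalgia        # 109
testing.per_patient_cost   # 124.0
```

For the trial side, `pgxcca gen-trial --seed 0 --out out/gen` writes a
synthetic patient-record CSV (column dictionary in
`pgxcca.synthetic_trial.COLUMN_DICTIONARY`) and
`pgxcca analyze-trial --load out/gen/trial.csv --out out/ana
--scenario pgx_cost_factor=0` produces arm summaries, the nested cost
ladder and scenario tables with cluster-bootstrap CIs.

## Layout

- `src/pgxcca/parameters.py` — model inputs, calibration, config I/O, CPI
  currency adjustment, PSA sampling
- `src/pgxcca/decision_model.py` — expected-value decision tree
- `src/pgxcca/psa.py` — probabilistic sensitivity analysis
- `src/pgxcca/microsim.py` — individual-level simulation oracle
- `src/pgxcca/synthetic_trial.py` — clustered synthetic trial generator
- `src/pgxcca/trial_analysis.py` — arm summaries, cluster bootstrap, cost
  ladders, scenarios
- `src/pgxcca/cli.py` — `pgxcca` command-line interface
- `docs/methods.md` — model assumptions, calibration and limitations
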