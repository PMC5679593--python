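# triage-econ

Cost-consequence evaluation of the 0/1-hour high-sensitivity cardiac
troponin T (hs-cTnT) triage algorithm for suspected acute myocardial
infarction (AMI) in the emergency department (ED), compared with ED
standard of care (SoC).

## The problem

5–10% of ED visits present with chest pain, but only a minority have
AMI. Standard troponin work-ups need serial sampling over many hours, so
most of these patients occupy an ED bed for most of a day. The 0/1-h
algorithm assigns each patient a zone from the baseline hs-cTnT
concentration *c₀* (ng/L) and the absolute 1-h change Δ = |c₁ − c₀|:

- **rule-out**: c₀ < A and Δ < B → discharge to outpatient stress testing;
- **rule-in**: c₀ ≥ C or Δ ≥ D → transfer for coronary angiography;
- **observation**: otherwise → continue serial sampling as under SoC
  (C > A, D > B; default cut-offs A=12, B=3, C=52, D=5 ng/L are
  configurable, not calibrated values).

This package estimates what adopting that rule would do to diagnostic
accuracy, ED length of stay (LoS), resource utilisation and per-patient
cost, for UK, German and Swiss payer perspectives (2016 £/€/CHF).

## The model

Four composable pieces, each a library module:

1. **Diagnostic accuracy** (`accuracy`). Zone-level sensitivity and
   specificity (the observation zone inherits the SoC working-diagnosis
   accuracy, sens 69% / spec 98%) are composed into overall rates by
   weighted average, and expanded into population TP/FN/TN/FP shares via
   the decision-tree identities TP = π·sens, FN = π·(1−sens),
   TN = (1−π)·spec, FP = (1−π)·(1−spec) for a zone group holding a
   fraction π of condition-positives.
2. **Length of stay** (`los`, `pathway`). SoC stays are modelled with
   accelerated-failure-time regressions log T = Xβ + σε (log-normal
   selected by AIC/BIC among six families; stays above 65 h excluded as
   implausible). The accelerated pathway composes zone stays from timing
   components: rule-in = 1.7 h (second draw) + 1.0 h (processing) =
   2.7 h; rule-out adds the alternative-diagnosis increment
   6.63 − 5.33 = 1.3 h to reach 4.0 h. Arm mean LoS is the
   category-share-weighted average of category stays.
3. **Costing** (`costing`). Per-patient expected cost = Σ share ×
   management cost per diagnostic category, split by care period
   (before/during/post ED + alternative-diagnosis work-up); false
   negatives are costed with a repeat inpatient AMI admission, false
   positives with unnecessary AMI treatment. Each country runs
   standalone in its own currency.
4. **One-way sensitivity analysis** (`owsa`). Every parameter is pushed
   to ±1 SE (rates, timings) or ±20% (unit costs), the pipeline is
   re-run at each bound, and parameters are ranked by outcome range for
   tornado display.

Because the underlying patient-level study data are not public, the
`cohort` module generates seeded synthetic cohorts with the calibrated
structure the analysis assumes (zone split ≈184/813/285 of 1,282, zone
prevalences from the published predictive values, log-normal LoS with
the published site/covariate coefficients, second draw 1.7 h); every
statistical claim in the test suite runs against these cohorts, and
`pipeline` exposes both a patient-level ("cohort") and an aggregate
("table") execution mode.

## Worked example

```python
from triage_econ import (PathwayTiming, classify, zone_los,
                         weighted_mean_los, savings, defaults)
from triage_econ.pathway import category_los_algorithm, category_los_soc
from triage_econ.costing import cost_consequence_table

print(classify(10.0, 11.0).zone)        # rule_out
print(classify(60.0, 61.0).zone)        # rule_in

timing = PathwayTiming()                # 1.7 h draw, 1.0 h processing
print(zone_los(timing, "rule_in"))      # 2.7
print(zone_los(timing, "rule_out"))     # 4.0

algo = weighted_mean_los(defaults.ALGORITHM_CATEGORY_SHARES,
                         category_los_algorithm(timing))
soc = weighted_mean_los({"all": defaults.SOC_CATEGORY_SHARES},
                        category_los_soc(timing))
print(round(algo.weighted_mean_hours, 2),  # 4.34
      round(soc.weighted_mean_hours, 2))   # 6.46

uk = cost_consequence_table("UK")
print(round(uk["algorithm_total"]), round(uk["soc_total"]),
      round(uk["savings_absolute"]), uk["savings_pct"])
# 2480 4561 2081 46
```

The accelerated pathway shortens the mean ED stay from 6.46 h to 4.34 h
(−2.12 h, 33%) and cuts UK per-patient cost from £4,561 to £2,480
(£2,081, 46%); German and Swiss perspectives save 38% and 40%.

## Analysis scripts

`analysis/01_simulate_cohort.py` … `06_owsa.py` are thin numbered
drivers that run the full study on a simulated cohort and write their
tables under `results/`. A `triage` CLI wraps the same library
(`triage simulate | classify | accuracy | fit-los | pathway | cost |
owsa | report`).

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator and its limits, numerical choices and known limitations.
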