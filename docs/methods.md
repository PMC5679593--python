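# Methods

## Decision problem and model structure

The package compares two ED triage strategies for suspected AMI — the
0/1-h hs-cTnT algorithm and the physicians' standard of care — on four
side-by-side outcomes: diagnostic accuracy, ED length of stay, resource
utilisation and per-patient cost. It is a cost-consequence design: no
ICERs, no QALYs, no aggregation across outcomes.

The population is partitioned twice: by zone group (decisive
rule-in/rule-out vs observation) and by diagnostic category (TP/FN/TN/FP
against adjudicated truth). All arm-level quantities are expectations
over that partition: a share table times a per-cell outcome table. The
central assumption throughout is that the observation zone behaves
exactly like standard of care — accuracy, stay, resource use and cost —
which is conservative in the sense that it dilutes whatever the decisive
zones gain.

## Triage rule

Zone assignment is a pure function of (baseline, |1-h change|) given
four cut-offs. The published text the analysis descends from does not
print the numeric cut-offs, so they are mandatory configuration; the
shipped defaults (rule-out < 12 ng/L and Δ < 3; rule-in ≥ 52 or Δ ≥ 5)
follow the widely used 0/1-h hs-cTnT rule and are labelled defaults, not
validated values. Boundary convention (strict rule-out, inclusive
rule-in) is itself configurable because published dialects differ.
Rule-in takes precedence in the implementation although the threshold
invariants (rule-out caps strictly below rule-in floors) make an overlap
impossible.

## Diagnostic accuracy

Confusion statistics use the standard estimators with Wilson score 95%
CIs (Clopper–Pearson available by option); Wilson was chosen because the
source material reports CIs without naming a method and Wilson behaves
well at the extreme specificities involved. Overall algorithm accuracy
is a weighted average over zone groups. Two weighting conventions are
implemented and reported side by side — condition-count weights (each
group's share of positives for sensitivity, of negatives for
specificity) and patient-count weights — because the published composite
(87%/96%) cannot be exactly re-derived from the printed zone rates under
any obvious weighting (condition weighting gives ≈ 89.5%). That
composite is therefore treated as descriptive, not as a target.

## Length of stay

SoC stays are complete (uncensored) durations, so every fit is a
complete-data MLE of the AFT form log T = Xβ + σε. Families: log-normal,
log-logistic, Weibull, exponential (σ ≡ 1), generalized gamma (Prentice
Q), and a proportional-hazards Gompertz. Generalized gamma and Gompertz
are flagged best-effort: the former's likelihood is nearly flat in Q
around the log-normal limit, the latter is not an AFT family and its
shape parameter degenerates on data without late-time hazard growth.
The analysis conclusion only requires the log-normal, which has an exact
closed-form MLE (OLS on log time) used directly, with the analytic
observed-information covariance. Other families start from the OLS
solution and use BFGS with a Nelder–Mead fallback; SEs come from the
numerically differentiated observed information.

Protocol steps mirror the source analysis: stays above 65 h (the
observed 90th-centile cut) are excluded as clinically implausible before
fitting; covariates are screened univariately at α = 10% with
likelihood-ratio tests (factors enter jointly); families are compared by
AIC (ties: BIC, then parameter count) with a fitted-vs-observed median
check in the comparison table.

Two separate stratum models (working-diagnosis AMI vs non-AMI) are
fitted rather than one pooled model with interactions, mirroring how the
coefficient sets are published. The published "Scale" entries (6.31,
6.18) are not interpretable as a log-normal σ given the reported mean
stays of 5.3/6.6 h (exp(6.3²/2) is astronomical); the package treats the
parametrisation as standard AFT and does not use those entries
numerically. Coefficient point values are carried as the generator's
ground truth; σ = 0.6 log-hours was chosen once as a realistic
right-skew for ED stays (90% of reference-pattern stays within roughly
×/÷ 2.7 of the median).

## Pathway composition

Accelerated-pathway stays are sums of timing components: second draw
1.7 h (study estimate, SE 0.03 h), result processing and discharge 1.0 h
(expert opinion; sensitivity range 1–3 h), and for rule-out an
alternative-diagnosis increment derived as the SoC non-AMI minus AMI
mean stay (6.63 − 5.33 = 1.3 h), applied zone-wide. Observation keeps
the SoC stratum means. Category → stay assignment follows the working
diagnosis (TP/FP travel the AMI path, FN/TN the non-AMI path), which is
what makes the arm table reproduce the published layout. Hours are
reported to 1 decimal; full precision is kept internally.

Resource-use mapping: before-ED events always pass through; decisive
zones keep during-ED events only up to the second draw; rule-in
re-issues late AMI procedures (angiography/CABG/PTCA/stent) as a
post-discharge work-up, rule-out replaces the post-discharge leg with
one outpatient stress test; observation passes through unchanged.
Misdiagnosed patients (FN/FP) additionally receive inpatient treatment
of their true condition, booked to the alternative-diagnosis cost
bucket.

## Costing

Each country (UK/DE/CH, 2016 £/€/CHF) is a standalone pipeline; no value
crosses a currency. Two modes: event mode costs explicit profiles
against a per-item unit-cost table (ED stay per bed-hour; staff time
either folded in or a separate item, site convention); table mode works
from published share-weighted cells — population category share ×
per-patient management cost — so arm totals are sums of cells. The
per-item unit-cost tables of the source study are not public; the
shipped YAML is synthetic placeholder data and labelled as such, while
table mode reproduces all published totals without it. Per-period cells
are rounded independently of the category subtotals in the published
grid, so subtotals take precedence in totals and period sums are checked
against them only within ±2 currency units.

## Sensitivity analysis

One-way only, by design: each parameter to ±1 SE (accuracy rates,
regression coefficients, timing means; SEs not printed in the main text
are user-supplied) or ±20% (unit costs), two pipeline evaluations per
parameter, ranked by outcome range; probabilities are clipped to [0, 1]
with a logged warning. In table mode the cost endpoint is insensitive to
timing parameters because the published cost cells already embed the
stay durations — a structural property of table mode, not a claim about
practice. No probabilistic SA is provided.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis needs and
nothing more:

- zone first (categorical at the 184/813/285-of-1,282 shares), then a
  troponin pair uniform over the zone's region of the (baseline, Δ)
  plane up to a 500 ng/L ceiling — zone membership is all that matters
  downstream, so no biological kinetics are modelled;
- adjudicated AMI per zone (defaults from the published predictive
  values: 0.77 rule-in, 0.01 rule-out, 48/285 observation), with an
  optional proportional rescale (clipped at 1, solved by bisection) to
  hit an overall prevalence target;
- working diagnosis as an independent Bernoulli flip of truth at
  (sens, spec) = (0.69, 0.98) — no covariate dependence;
- stays log-normal from the ground-truth coefficient sets by
  working-diagnosis stratum; optional planted outliers in 69–101 h with
  an optional cap on base draws for exact-exclusion experiments;
- second-draw times truncated-normal (floor 0.75 h, SD 0.03·√1282 ≈
  1.07 h — the study-level SE scaled back to patient level), with the
  pre-truncation location solved so the *truncated* mean hits 1.7 h;
- alternative conditions from a configurable categorical (unstable
  angina, arrhythmia, GI, musculoskeletal, anxiety, other; proportions
  are free config);
- resource events as per-item Bernoulli draws with placeholder
  probabilities (the study's utilisation table is not public) — any real
  costing run must supply its own.

What passing cohort-level tests shows, therefore, is that the machinery
is correct under the stated generating assumptions — independence of the
working diagnosis from covariates, exactly log-normal stays, uniform
within-zone troponin — not that real ED data satisfy them. Observation
counts in the published tables disagree internally (287 vs 237 non-AMI);
the generator uses 285 total with 48 AMI, both configurable.

## Problem sizes and numerics

Default simulated cohorts are the study size (n = 1,282); calibration
convergence checks use n = 50,000–100,000; parameter-recovery coverage
uses 200 cohorts of n = 2,000 and screening calibration 1,000 null
replicates of n = 2,000, sizes at which binomial/asymptotic noise is
well inside the asserted bands. All randomness flows from a single
integer seed through `numpy.random.default_rng`. Degenerate inputs are
rejected with named offenders (constant or collinear design columns,
negative troponin with file line numbers, missing unit-cost items,
non-normalised share vectors); empty cohorts are legal no-ops.

## Known limitations

- The accelerated arm's stays and resource use are modelled consequences
  of an implementation elicited from clinicians, not observations; the
  physicians were blinded to the algorithm in the underlying study.
- Costs are payer-perspective and setting-specific; nothing transfers
  across countries, and outpatient burden shifted out of the ED (stress
  tests) is counted only as a cost item, not a societal consequence.
- Site effects are associational covariates, not causal estimates.
- The generator's independence assumptions above; in particular SoC
  accuracy does not vary by site or covariates.
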