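"""Seeded synthetic ED chest-pain cohorts.

Real patient-level data from multicentre troponin studies are not
publicly deposited, so every downstream stage runs against synthetic
cohorts that reproduce the statistical structure the analysis relies on:

* triage-zone shares (rule-in / rule-out / observation) hit configured
  targets in expectation, and the troponin pair of each patient is drawn
  inside the region its zone occupies in the (baseline, 1-h delta) plane
  — applying the triage thresholds to the generated values recovers the
  sampled zone deterministically;
* adjudicated AMI status is sampled per zone (rule-in mostly AMI,
  rule-out almost never), with an optional rescaling to an overall
  prevalence target;
* the ED working diagnosis is a sensitivity/specificity-driven flip of
  the adjudicated truth, independent across patients;
* length of stay is log-normal with site and covariate effects from a
  configurable ground-truth coefficient set, stratified by working
  diagnosis;
* the admission-to-second-draw time is truncated normal.

Resource events are per-item Bernoulli draws; the default item list and
probabilities are plain placeholders (the study's per-item utilisation
table is not public) and should be treated as user-supplied inputs.

Troponin kinetics are *not* modelled biologically: only zone membership
matters downstream, so within-zone marginals are uniform over the
threshold-defined region up to a configurable ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .los import FACTOR_LEVELS, build_design
from .triage import (
    OBSERVATION,
    RULE_IN,
    RULE_OUT,
    DEFAULT_THRESHOLDS,
    TriageThresholds,
)

logger = logging.getLogger(__name__)

SITES = FACTOR_LEVELS["site"][0]

PATIENT_COLUMNS = [
    "patient_id",
    "site",
    "age_years",
    "age_category",
    "sex",
    "onset_hours",
    "peak_hours",
    "dyspnea",
    "pain_intensity_positive",
    "bp_category",
    "hr_category",
    "chf_history",
    "true_dx",
    "alt_condition",
    "tnt_baseline",
    "tnt_1h",
    "t_second_draw",
    "soc_dx",
    "soc_los",
]
EVENT_COLUMNS = ["patient_id", "item", "period", "time_offset"]

RESOURCE_ITEMS = (
    "blood draw",
    "ECG",
    "CT scan",
    "MRI scan",
    "echocardiography",
    "invasive angiography",
    "CABG",
    "PTCA",
    "stent",
    "outpatient stress test",
)

#: alternative (non-AMI) working conditions; proportions are free config
ALT_CONDITIONS = (
    "unstable angina",
    "arrhythmia",
    "gastrointestinal",
    "musculoskeletal",
    "anxiety",
    "other",
)
ALT_CONDITION_PROBS = (0.15, 0.15, 0.2, 0.25, 0.15, 0.10)

#: placeholder per-item event probabilities: item -> (prob, period, offset
#: in hours).  User-supplied in any real costing run.
DEFAULT_RU_PROBS: dict[str, tuple[float, str, float]] = {
    "ECG": (0.95, "during_ED", 0.2),
    "CT scan": (0.08, "during_ED", 2.5),
    "MRI scan": (0.02, "during_ED", 3.0),
    "echocardiography": (0.20, "during_ED", 2.8),
    "invasive angiography": (0.15, "during_ED", 3.5),
    "PTCA": (0.08, "during_ED", 4.0),
    "stent": (0.07, "during_ED", 4.0),
    "CABG": (0.01, "post_ED", 30.0),
}


@dataclass(frozen=True)
class LoSGroundTruth:
    """Log-normal AFT ground truth used to draw stays (log-hour scale)."""

    coeffs_ami: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.LOS_COEFFS_AMI)
    )
    coeffs_nonami: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.LOS_COEFFS_NONAMI)
    )
    covariates_ami: tuple[str, ...] = defaults.AMI_COVARIATES
    covariates_nonami: tuple[str, ...] = defaults.NONAMI_COVARIATES
    sigma: float = defaults.LOS_SIGMA


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults emulate the study cohort.

    ``zone_target_shares`` orders (rule-in, rule-out, observation);
    ``zone_ami_prevalence`` gives per-zone adjudicated-AMI probability
    (defaults follow the published zone-level predictive values: rule-in
    PPV 0.77, rule-out 1-NPV 0.01, observation 48/285).  When
    ``ami_prevalence`` is set, zone prevalences are rescaled (with
    clipping) so the overall prevalence converges to it.
    ``second_draw_sd`` defaults to the study-level SE scaled back to a
    patient-level SD (0.03 x sqrt(1282) ~ 1.07 h), truncated at 0.75 h.
    """

    n_patients: int = defaults.N_STUDY
    zone_target_shares: tuple[float, float, float] = (
        defaults.ZONE_SHARES["rule_in"],
        defaults.ZONE_SHARES["rule_out"],
        defaults.ZONE_SHARES["observation"],
    )
    zone_ami_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            RULE_IN: 0.77,
            RULE_OUT: 0.01,
            OBSERVATION: defaults.OBSERVATION_AMI_COUNT
            / defaults.ZONE_COUNTS["observation"],
        }
    )
    ami_prevalence: float | None = None
    soc_sensitivity: float = defaults.SOC_ACCURACY[0]
    soc_specificity: float = defaults.SOC_ACCURACY[1]
    second_draw_mean: float = defaults.SECOND_DRAW_MEAN_H
    second_draw_sd: float = defaults.SECOND_DRAW_SE_H * np.sqrt(defaults.N_STUDY)
    second_draw_min: float = 0.75
    los_generator: LoSGroundTruth = field(default_factory=LoSGroundTruth)
    site_weights: tuple[float, ...] | None = None  # uniform when None
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS
    troponin_max: float = 500.0
    alt_conditions: tuple[str, ...] = ALT_CONDITIONS
    alt_condition_probs: tuple[float, ...] = ALT_CONDITION_PROBS
    ru_item_probs: Mapping[str, tuple[float, str, float]] = field(
        default_factory=lambda: dict(DEFAULT_RU_PROBS)
    )
    n_planted_outliers: int = 0
    outlier_range_hours: tuple[float, float] = (69.0, 101.0)
    base_los_cap_hours: float | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        shares = np.asarray(self.zone_target_shares, dtype=float)
        if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("zone_target_shares must be non-negative and sum to 1")
        for name in ("soc_sensitivity", "soc_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ami_prevalence is not None and not 0.0 <= self.ami_prevalence <= 1.0:
            raise ValueError("ami_prevalence must lie in [0, 1]")
        for z, p in self.zone_ami_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"zone prevalence for {z!r} must lie in [0, 1]")
        if self.site_weights is not None:
            w = np.asarray(self.site_weights, dtype=float)
            if len(w) != len(SITES) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("site_weights must be 12 non-negative values summing to 1")
        if abs(sum(self.alt_condition_probs) - 1.0) > 1e-9:
            raise ValueError("alt_condition_probs must sum to 1")
        if self.second_draw_min <= 0:
            raise ValueError("second_draw_min must be > 0")


@dataclass
class Cohort:
    """A synthetic cohort: one row per patient plus long-format events."""

    patients: pd.DataFrame
    events: pd.DataFrame

    def __len__(self) -> int:
        return len(self.patients)


def _effective_zone_prevalence(config: CohortConfig) -> dict[str, float]:
    """Rescale zone prevalences so the cohort hits ``ami_prevalence``.

    Solves for a common multiplier t with per-zone clipping at 1 such
    that sum_z share_z * min(1, t * p_z) equals the target.
    """
    zones = (RULE_IN, RULE_OUT, OBSERVATION)
    shares = dict(zip(zones, config.zone_target_shares))
    base = {z: config.zone_ami_prevalence.get(z, 0.0) for z in zones}
    target = config.ami_prevalence
    if target is None:
        return base
    derived = sum(shares[z] * base[z] for z in zones)
    if target == 0.0:
        return {z: 0.0 for z in zones}
    if derived == 0.0:
        raise ValueError("cannot rescale all-zero zone prevalences to a positive target")

    def overall(t: float) -> float:
        return sum(shares[z] * min(1.0, t * base[z]) for z in zones)

    if target > overall(1e6):
        raise ValueError(f"ami_prevalence={target} unreachable given zone structure")
    lo, hi = 0.0, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if overall(mid) < target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return {z: min(1.0, t * base[z]) for z in zones}


def _draw_troponin(
    zone: np.ndarray, rng: np.random.Generator, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform draws inside each zone's region of the (baseline, delta) plane."""
    t = config.thresholds
    n = len(zone)
    baseline = np.empty(n)
    delta = np.empty(n)

    m = zone == RULE_OUT
    k = int(m.sum())
    baseline[m] = rng.uniform(0.0, t.rule_out_baseline_max, k)
    lo = np.maximum(-t.rule_out_delta_max, -baseline[m])
    delta[m] = rng.uniform(lo, t.rule_out_delta_max)

    m = zone == OBSERVATION
    k = int(m.sum())
    baseline[m] = rng.uniform(t.rule_out_baseline_max, t.rule_in_baseline_min, k)
    delta[m] = rng.uniform(-t.rule_in_delta_min, t.rule_in_delta_min, k)

    m = zone == RULE_IN
    k = int(m.sum())
    high = rng.random(k) < 0.5  # high-baseline vs dynamic-rise presentation
    b = np.where(
        high,
        rng.uniform(t.rule_in_baseline_min, config.troponin_max, k),
        rng.uniform(0.0, t.rule_in_baseline_min, k),
    )
    d = np.where(
        high,
        rng.uniform(-t.rule_in_delta_min, t.rule_in_delta_min, k),
        rng.uniform(t.rule_in_delta_min, t.rule_in_delta_min + 50.0, k),
    )
    d = np.maximum(d, -b)  # keep the 1-h value non-negative
    baseline[m], delta[m] = b, d

    tnt_1h = np.maximum(baseline + delta, 0.0)
    return baseline, tnt_1h


def _draw_second_draw_times(
    target_mean: float,
    sd: float,
    lower: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lower-truncated normal draws whose *truncated* mean hits the target.

    Truncation at ``lower`` inflates the mean of a normal located at the
    target, so the pre-truncation location is solved for numerically.
    """
    if target_mean <= lower:
        raise ValueError("second_draw_mean must exceed second_draw_min")

    def truncated_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    from scipy.optimize import brentq

    lo = target_mean - 10.0 * sd
    loc = brentq(lambda m: truncated_mean(m) - target_mean, lo, target_mean)
    a = (lower - loc) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=n, random_state=rng)


def _draw_los(
    patients: pd.DataFrame, rng: np.random.Generator, gt: LoSGroundTruth
) -> np.ndarray:
    """Log-normal stays from the ground-truth model, by working diagnosis."""
    log_los = np.empty(len(patients))
    for stratum, coeffs, covs in (
        ("AMI", gt.coeffs_ami, gt.covariates_ami),
        ("non-AMI", gt.coeffs_nonami, gt.covariates_nonami),
    ):
        mask = (patients["soc_dx"] == stratum).to_numpy()
        if not mask.any():
            continue
        sub = patients.loc[mask]
        X, names = build_design(sub, covs)
        beta = np.array([coeffs.get(nm, 0.0) for nm in names])
        log_los[mask] = X @ beta + gt.sigma * rng.standard_normal(int(mask.sum()))
    return np.exp(log_los)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a seeded synthetic cohort per the configuration.

    Deterministic for a fixed ``config.rng_seed``: two calls with the same
    config return field-identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients

    site_w = (
        np.full(len(SITES), 1.0 / len(SITES))
        if config.site_weights is None
        else np.asarray(config.site_weights, dtype=float)
    )
    site = rng.choice(SITES, size=n, p=site_w)
    age_years = np.round(np.clip(rng.normal(61.0, 15.0, n), 18.0, 95.0), 1)
    age_category = np.select(
        [age_years <= 65.0, age_years <= 75.0], ["<=65", "65-75"], default=">75"
    )
    sex = np.where(rng.random(n) < 0.6, "male", "female")
    onset_hours = rng.uniform(0.5, 6.0, n)
    peak_hours = rng.uniform(0.0, onset_hours)
    dyspnea = np.where(rng.random(n) < 0.25, "yes", "no")
    pain_pos = np.where(rng.random(n) < 0.9, "1", "0")
    bp_category = rng.choice(["below", "normal", "above"], size=n, p=[0.10, 0.75, 0.15])
    hr_category = rng.choice(["below", "normal", "above"], size=n, p=[0.10, 0.75, 0.15])
    chf_history = rng.choice(["no", "yes", "unknown"], size=n, p=[0.88, 0.10, 0.02])

    zone = rng.choice(
        [RULE_IN, RULE_OUT, OBSERVATION], size=n, p=config.zone_target_shares
    )
    zone_prev = _effective_zone_prevalence(config)
    p_ami = np.vectorize(zone_prev.get)(zone).astype(float)
    is_ami = rng.random(n) < p_ami
    true_dx = np.where(is_ami, "AMI", "non-AMI")
    alt_condition = np.where(
        is_ami,
        "",
        rng.choice(config.alt_conditions, size=n, p=config.alt_condition_probs),
    )

    tnt_baseline, tnt_1h = _draw_troponin(zone, rng, config)

    # working diagnosis: independent Bernoulli flip of truth
    u = rng.random(n)
    soc_pos = np.where(is_ami, u < config.soc_sensitivity, u > config.soc_specificity)
    soc_dx = np.where(soc_pos, "AMI", "non-AMI")

    t_second = _draw_second_draw_times(
        config.second_draw_mean,
        config.second_draw_sd,
        config.second_draw_min,
        n,
        rng,
    )

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "site": site,
            "age_years": age_years,
            "age_category": age_category,
            "sex": sex,
            "onset_hours": np.round(onset_hours, 3),
            "peak_hours": np.round(peak_hours, 3),
            "dyspnea": dyspnea,
            "pain_intensity_positive": pain_pos,
            "bp_category": bp_category,
            "hr_category": hr_category,
            "chf_history": chf_history,
            "true_dx": true_dx,
            "alt_condition": alt_condition,
            "tnt_baseline": np.round(tnt_baseline, 4),
            "tnt_1h": np.round(tnt_1h, 4),
            "t_second_draw": np.round(t_second, 4),
            "soc_dx": soc_dx,
        }
    )

    los = _draw_los(patients, rng, config.los_generator)
    if config.base_los_cap_hours is not None:
        los = np.minimum(los, config.base_los_cap_hours - 1e-6)
    if config.n_planted_outliers:
        if config.n_planted_outliers > n:
            raise ValueError("more planted outliers than patients")
        idx = rng.choice(n, size=config.n_planted_outliers, replace=False)
        lo, hi = config.outlier_range_hours
        los[idx] = rng.uniform(lo, hi, config.n_planted_outliers)
    patients["soc_los"] = np.round(los, 4)

    events = _draw_events(patients, rng, config)
    return Cohort(patients=patients, events=events)


def _draw_events(
    patients: pd.DataFrame, rng: np.random.Generator, config: CohortConfig
) -> pd.DataFrame:
    """Per-item Bernoulli event draws; every patient gets two blood draws."""
    n = len(patients)
    frames = [
        pd.DataFrame(
            {
                "patient_id": np.repeat(patients["patient_id"].to_numpy(), 2),
                "item": "blood draw",
                "period": "during_ED",
                "time_offset": np.column_stack(
                    [np.zeros(n), patients["t_second_draw"].to_numpy()]
                ).ravel(),
            }
        )
    ]
    for item, (prob, period, offset) in config.ru_item_probs.items():
        mask = rng.random(n) < prob
        if not mask.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patients.loc[mask, "patient_id"].to_numpy(),
                    "item": item,
                    "period": period,
                    "time_offset": float(offset),
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return events.sort_values(["patient_id", "time_offset"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# persistence


class CohortValidationError(ValueError):
    """A cohort file violates the schema; message carries line numbers."""


def _validate_patients(df: pd.DataFrame) -> None:
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"missing columns: {sorted(missing)}")
    problems: list[str] = []

    def check(mask: pd.Series, message: str) -> None:
        for i in df.index[mask][:5]:
            problems.append(f"line {i + 2}: {message}")

    check(df["tnt_baseline"] < 0, "tnt_baseline is negative")
    check(df["tnt_1h"] < 0, "tnt_1h is negative")
    check(df["t_second_draw"] <= 0, "t_second_draw must be > 0")
    check(df["soc_los"] <= 0, "soc_los must be > 0")
    check(~df["true_dx"].isin(["AMI", "non-AMI"]), "true_dx not in {AMI, non-AMI}")
    check(~df["soc_dx"].isin(["AMI", "non-AMI"]), "soc_dx not in {AMI, non-AMI}")
    expected_cat = np.select(
        [df["age_years"] <= 65.0, df["age_years"] <= 75.0],
        ["<=65", "65-75"],
        default=">75",
    )
    check(
        pd.Series(df["age_category"].to_numpy() != expected_cat, index=df.index),
        "age_category inconsistent with age_years",
    )
    if problems:
        raise CohortValidationError("; ".join(problems))


def _events_path(path: str) -> str:
    return (
        path[: -len(".csv")] + "_events.csv" if path.endswith(".csv") else path + "_events.csv"
    )


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write patients to ``path`` and events to ``*_events.csv``."""
    cohort.patients.to_csv(path, index=False)
    cohort.events.to_csv(_events_path(path), index=False)


def read_cohort(path: str) -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`.

    An empty patients file yields an empty cohort with a logged warning.
    """
    try:
        patients = pd.read_csv(
            path, dtype={"pain_intensity_positive": str, "patient_id": str}
        )
    except pd.errors.EmptyDataError:
        patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    if len(patients) == 0:
        warnings.warn(f"cohort file {path!r} is empty", stacklevel=2)
        logger.warning("cohort file %r is empty", path)
        return Cohort(
            patients=pd.DataFrame(columns=PATIENT_COLUMNS),
            events=pd.DataFrame(columns=EVENT_COLUMNS),
        )
    if "alt_condition" in patients.columns:
        # AMI patients carry no alternative condition (blank cell)
        patients["alt_condition"] = patients["alt_condition"].fillna("")
    _validate_patients(patients)
    try:
        events = pd.read_csv(_events_path(path), dtype={"patient_id": str})
    except (FileNotFoundError, pd.errors.EmptyDataError):
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return Cohort(patients=patients, events=events)
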