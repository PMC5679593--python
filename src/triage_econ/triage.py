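"""0/1-hour hs-cTnT triage rule: rule-out / rule-in / observation.

The decision rule assigns a zone from the baseline hs-cTnT concentration
(ng/L) and the absolute change after one hour:

* rule-out   — baseline below a low cut-off AND |delta| below a small
               change cut-off (AMI very unlikely; discharge to outpatient
               work-up);
* rule-in    — baseline above a high cut-off OR |delta| above a large
               change cut-off (AMI likely; transfer for angiography);
* observation — everything in between (serial sampling continues).

The numeric cut-offs are mandatory configuration.  The defaults shipped
here (rule-out: baseline < 12 ng/L and delta < 3 ng/L; rule-in: baseline
>= 52 ng/L or delta >= 5 ng/L) follow the published 0/1-h hs-cTnT
algorithm literature; they are defaults, not calibrated values, and any
site deploying a different assay dialect must supply its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

RULE_IN = "rule_in"
RULE_OUT = "rule_out"
OBSERVATION = "observation"
ZONES = (RULE_IN, RULE_OUT, OBSERVATION)


class UnclassifiableError(ValueError):
    """Raised when a patient cannot be zoned (e.g. missing 1-h draw)."""


@dataclass(frozen=True)
class TriageThresholds:
    """Cut-offs of the 0/1-h decision rule, all in ng/L.

    ``rule_out_strict`` / ``rule_in_inclusive`` control the boundary
    convention (default: rule-out uses strict ``<``, rule-in uses ``>=``),
    exposed because published dialects differ.
    """

    rule_out_baseline_max: float = 12.0
    rule_out_delta_max: float = 3.0
    rule_in_baseline_min: float = 52.0
    rule_in_delta_min: float = 5.0
    rule_out_strict: bool = True
    rule_in_inclusive: bool = True

    def __post_init__(self) -> None:
        vals = (
            self.rule_out_baseline_max,
            self.rule_out_delta_max,
            self.rule_in_baseline_min,
            self.rule_in_delta_min,
        )
        if any(v < 0 for v in vals):
            raise ValueError("triage thresholds must be non-negative")
        if not self.rule_out_baseline_max < self.rule_in_baseline_min:
            raise ValueError(
                "rule_out_baseline_max must be < rule_in_baseline_min"
            )
        if not self.rule_out_delta_max < self.rule_in_delta_min:
            raise ValueError("rule_out_delta_max must be < rule_in_delta_min")


DEFAULT_THRESHOLDS = TriageThresholds()


@dataclass(frozen=True)
class TriageResult:
    zone: str
    baseline: float
    delta: float  # absolute 1-h change, ng/L


def classify(
    baseline: float,
    tnt_1h: float,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
) -> TriageResult:
    """Zone a single patient from the paired troponin measurements.

    Rule-in takes precedence over rule-out; the threshold invariants make
    an overlap impossible, but the ordering is fixed for safety.
    """
    if baseline is None or tnt_1h is None:
        raise UnclassifiableError("both troponin draws are required")
    if isinstance(baseline, float) and math.isnan(baseline):
        raise UnclassifiableError("baseline hs-cTnT is missing (NaN)")
    if isinstance(tnt_1h, float) and math.isnan(tnt_1h):
        raise UnclassifiableError("1-h hs-cTnT is missing (NaN)")
    if baseline < 0 or tnt_1h < 0:
        raise ValueError("troponin concentrations must be >= 0 ng/L")

    delta = abs(tnt_1h - baseline)
    t = thresholds
    if t.rule_in_inclusive:
        rule_in = baseline >= t.rule_in_baseline_min or delta >= t.rule_in_delta_min
    else:
        rule_in = baseline > t.rule_in_baseline_min or delta > t.rule_in_delta_min
    if t.rule_out_strict:
        rule_out = baseline < t.rule_out_baseline_max and delta < t.rule_out_delta_max
    else:
        rule_out = baseline <= t.rule_out_baseline_max and delta <= t.rule_out_delta_max

    if rule_in:
        zone = RULE_IN
    elif rule_out:
        zone = RULE_OUT
    else:
        zone = OBSERVATION
    return TriageResult(zone=zone, baseline=float(baseline), delta=float(delta))


def classify_vector(
    baseline: np.ndarray,
    tnt_1h: np.ndarray,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised zone assignment; same semantics as :func:`classify`."""
    baseline = np.asarray(baseline, dtype=float)
    tnt_1h = np.asarray(tnt_1h, dtype=float)
    if np.isnan(baseline).any() or np.isnan(tnt_1h).any():
        raise UnclassifiableError("missing troponin values in cohort")
    if (baseline < 0).any() or (tnt_1h < 0).any():
        raise ValueError("troponin concentrations must be >= 0 ng/L")
    delta = np.abs(tnt_1h - baseline)
    t = thresholds
    if t.rule_in_inclusive:
        rule_in = (baseline >= t.rule_in_baseline_min) | (delta >= t.rule_in_delta_min)
    else:
        rule_in = (baseline > t.rule_in_baseline_min) | (delta > t.rule_in_delta_min)
    if t.rule_out_strict:
        rule_out = (baseline < t.rule_out_baseline_max) & (delta < t.rule_out_delta_max)
    else:
        rule_out = (baseline <= t.rule_out_baseline_max) & (delta <= t.rule_out_delta_max)
    zones = np.full(baseline.shape, OBSERVATION, dtype=object)
    zones[rule_out] = RULE_OUT
    zones[rule_in] = RULE_IN  # precedence: rule-in wins (cannot overlap)
    return zones


def classify_cohort(
    cohort: pd.DataFrame,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.Series, dict[str, float]]:
    """Zone every patient and summarise zone shares.

    Parameters
    ----------
    cohort : DataFrame with ``tnt_baseline`` and ``tnt_1h`` columns (ng/L)
        and a ``patient_id`` column used to label per-record errors.

    Returns
    -------
    (zones, shares) where ``zones`` is a Series aligned to the cohort index
    and ``shares`` maps zone -> fraction of patients (sums to 1; empty dict
    for an empty cohort).
    """
    if len(cohort) == 0:
        return pd.Series([], dtype=object, name="zone"), {}
    try:
        zones = classify_vector(
            cohort["tnt_baseline"].to_numpy(),
            cohort["tnt_1h"].to_numpy(),
            thresholds,
        )
    except (ValueError, UnclassifiableError):
        # fall back to per-record classification to name the offender
        for _, row in cohort.iterrows():
            try:
                classify(row["tnt_baseline"], row["tnt_1h"], thresholds)
            except (ValueError, UnclassifiableError) as exc:
                raise type(exc)(
                    f"patient {row.get('patient_id', '?')}: {exc}"
                ) from exc
        raise  # pragma: no cover - vector error without row error
    zones = pd.Series(zones, index=cohort.index, name="zone")
    shares = (zones.value_counts(normalize=True)).to_dict()
    for z in ZONES:
        shares.setdefault(z, 0.0)
    return zones, shares
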