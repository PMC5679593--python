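"""Clinical pathway model: zone LoS composition and arm-level summaries.

Under the accelerated pathway, rule-in and rule-out patients leave the ED
once the 1-h result is processed: their stay is the admission-to-second-
draw time plus a sample-analysis/discharge-processing time; rule-out
patients additionally absorb the alternative-diagnosis work-up increment,
derived as the standard-of-care non-AMI minus AMI mean stay.  Observation
patients stay exactly as under standard of care.

Arm mean LoS is the diagnostic-category-share-weighted average of
category stays.  Category -> stay assignment follows the *working*
diagnosis: TP and FP patients travel the AMI path (rule-in under the
algorithm), FN and TN the non-AMI path (rule-out).

Resource-use mapping applies the same pathway logic to standard-of-care
event profiles: events before ED admission are kept; during-ED events are
truncated at the second draw for decisive zones; the post-discharge leg
is an AMI procedure work-up for rule-in, a single outpatient stress test
for rule-out, and the unchanged profile for observation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from . import defaults
from .accuracy import CATEGORIES
from .triage import OBSERVATION, RULE_IN, RULE_OUT

#: procedures that constitute the post-discharge AMI work-up for rule-in
AMI_PROCEDURES = ("invasive angiography", "CABG", "PTCA", "stent")
STRESS_TEST = "outpatient stress test"


@dataclass(frozen=True)
class PathwayTiming:
    """Timing components of the accelerated pathway, in hours.

    ``t_alt_dx`` defaults to the derived non-AMI minus AMI
    standard-of-care mean-stay difference.
    """

    t_second_draw: float = defaults.SECOND_DRAW_MEAN_H
    t_processing: float = defaults.PROCESSING_TIME_H
    soc_mean_los_ami: float = defaults.SOC_MEAN_LOS_AMI_H
    soc_mean_los_nonami: float = defaults.SOC_MEAN_LOS_NONAMI_H
    t_alt_dx: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_second_draw", "t_processing", "soc_mean_los_ami",
                     "soc_mean_los_nonami"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 hours")
        if self.t_alt_dx is not None and self.t_alt_dx < 0:
            raise ValueError("t_alt_dx must be >= 0 hours")

    @property
    def alt_dx_increment(self) -> float:
        if self.t_alt_dx is not None:
            return self.t_alt_dx
        return self.soc_mean_los_nonami - self.soc_mean_los_ami


def zone_los(timing: PathwayTiming, zone: str) -> float:
    """Mean ED LoS (hours) for a pathway zone.

    ``zone`` is ``rule_in``, ``rule_out``, ``observation_ami`` or
    ``observation_nonami`` (observation keeps the standard-of-care
    stratum means).
    """
    if zone == RULE_IN:
        return timing.t_second_draw + timing.t_processing
    if zone == RULE_OUT:
        return timing.t_second_draw + timing.alt_dx_increment + timing.t_processing
    if zone in ("observation_ami", f"{OBSERVATION}_ami"):
        return timing.soc_mean_los_ami
    if zone in ("observation_nonami", f"{OBSERVATION}_nonami"):
        return timing.soc_mean_los_nonami
    raise ValueError(f"unknown zone {zone!r}")


def category_los_algorithm(timing: PathwayTiming) -> dict[str, dict[str, float]]:
    """Category -> mean stay under the 1-h arm, per zone group.

    Working diagnosis drives the path: TP/FP -> rule-in stay, FN/TN ->
    rule-out stay in the decisive group; the observation group keeps the
    standard-of-care stratum means (TP/FP -> AMI, FN/TN -> non-AMI).
    """
    ri = zone_los(timing, RULE_IN)
    ro = zone_los(timing, RULE_OUT)
    return {
        "rule_in_out": {"TP": ri, "FN": ro, "TN": ro, "FP": ri},
        "observation": {
            "TP": timing.soc_mean_los_ami,
            "FN": timing.soc_mean_los_nonami,
            "TN": timing.soc_mean_los_nonami,
            "FP": timing.soc_mean_los_ami,
        },
    }


def category_los_soc(timing: PathwayTiming) -> dict[str, dict[str, float]]:
    """Category -> mean stay under standard of care (single group)."""
    return {
        "all": {
            "TP": timing.soc_mean_los_ami,
            "FN": timing.soc_mean_los_nonami,
            "TN": timing.soc_mean_los_nonami,
            "FP": timing.soc_mean_los_ami,
        }
    }


@dataclass(frozen=True)
class ArmLoSSummary:
    """Share-weighted mean stay of one arm, with per-cell detail."""

    arm: str
    weighted_mean_hours: float
    shares: Mapping[str, Mapping[str, float]]
    category_los: Mapping[str, Mapping[str, float]]
    reduction_vs_comparator_hours: float | None = None
    reduction_vs_comparator_pct: float | None = None


def weighted_mean_los(
    shares: Mapping[str, Mapping[str, float]],
    category_los: Mapping[str, Mapping[str, float]],
    arm: str = "",
) -> ArmLoSSummary:
    """Exact share-weighted mean stay over zone groups x categories.

    ``shares`` must cover the whole population (cells sum to 1 within
    1e-6) and use the same group/category layout as ``category_los``.
    """
    total_share = 0.0
    weighted = 0.0
    for group, cats in shares.items():
        if group not in category_los:
            raise ValueError(f"no category LoS for zone group {group!r}")
        for cat, share in cats.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if cat not in category_los[group]:
                raise ValueError(f"no LoS for ({group!r}, {cat!r})")
            total_share += share
            weighted += share * category_los[group][cat]
    if abs(total_share - 1.0) > 1e-6:
        raise ValueError(f"shares must sum to 1, got {total_share:.6f}")
    return ArmLoSSummary(
        arm=arm,
        weighted_mean_hours=weighted,
        shares=shares,
        category_los=category_los,
    )


def compare_arms(arm: ArmLoSSummary, comparator: ArmLoSSummary) -> ArmLoSSummary:
    """Attach absolute and percent stay reduction versus a comparator."""
    diff = comparator.weighted_mean_hours - arm.weighted_mean_hours
    pct = diff / comparator.weighted_mean_hours if comparator.weighted_mean_hours else float("nan")
    return replace(
        arm,
        reduction_vs_comparator_hours=diff,
        reduction_vs_comparator_pct=pct,
    )


# ---------------------------------------------------------------------------
# resource-use mapping


def map_resources(
    events: pd.DataFrame,
    zones: pd.Series,
    timing: PathwayTiming,
) -> pd.DataFrame:
    """Rewrite standard-of-care event profiles for the 1-h arm.

    Parameters
    ----------
    events : long-format table with columns ``patient_id``, ``item``,
        ``period`` (before_ED/during_ED/post_ED) and ``time_offset``
        (hours from ED admission).
    zones : patient_id -> zone assignment.

    Rules: before-ED events pass through for everyone; observation
    patients keep their whole profile.  Rule-in/rule-out patients keep
    during-ED events only up to the second blood draw; their
    standard-of-care post-second-draw AMI procedures are re-issued as a
    post-discharge work-up for rule-in, while rule-out patients instead
    receive one outpatient stress test after discharge.
    """
    required = {"patient_id", "item", "period", "time_offset"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    zone_of = zones.to_dict() if not isinstance(zones, dict) else zones
    unknown_zones = set(zone_of.values()) - {RULE_IN, RULE_OUT, OBSERVATION}
    if unknown_zones:
        raise ValueError(f"unknown zone label(s) {sorted(unknown_zones)}")

    out_rows: list[dict] = []
    for pid, grp in events.groupby("patient_id", sort=False):
        zone = zone_of.get(pid)
        if zone is None:
            raise ValueError(f"patient {pid!r} has events but no zone")
        if zone == OBSERVATION:
            out_rows.extend(grp.to_dict("records"))
            continue
        for row in grp.to_dict("records"):
            if row["period"] == "before_ED":
                out_rows.append(row)
            elif row["period"] == "during_ED":
                if row["time_offset"] <= timing.t_second_draw:
                    out_rows.append(row)
                elif zone == RULE_IN and row["item"] in AMI_PROCEDURES:
                    moved = dict(row)
                    moved["period"] = "post_ED"
                    out_rows.append(moved)
            elif row["period"] == "post_ED":
                if zone == RULE_IN:
                    out_rows.append(row)
                # rule-out: SoC post-discharge events replaced by stress test
            else:
                raise ValueError(f"unknown period {row['period']!r}")
        if zone == RULE_OUT:
            out_rows.append(
                {
                    "patient_id": pid,
                    "item": STRESS_TEST,
                    "period": "post_ED",
                    "time_offset": zone_los(timing, RULE_OUT),
                }
            )
    # patients with a zone but no events: rule-out still gets the stress test
    for pid, zone in zone_of.items():
        if zone == RULE_OUT and pid not in set(events["patient_id"]):
            out_rows.append(
                {
                    "patient_id": pid,
                    "item": STRESS_TEST,
                    "period": "post_ED",
                    "time_offset": zone_los(timing, RULE_OUT),
                }
            )
    return pd.DataFrame(out_rows, columns=["patient_id", "item", "period", "time_offset"])
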