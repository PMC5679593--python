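"""Pathway composition: zone LoS, arm-weighted means, resource mapping."""

import numpy as np
import pandas as pd
import pytest

from triage_econ import defaults
from triage_econ.pathway import (
    AMI_PROCEDURES,
    STRESS_TEST,
    PathwayTiming,
    category_los_algorithm,
    category_los_soc,
    compare_arms,
    map_resources,
    weighted_mean_los,
    zone_los,
)
from triage_econ.pipeline import TableModeConfig, evaluate_table_mode

ALGO_SHARES = defaults.ALGORITHM_CATEGORY_SHARES
SOC_SHARES = {"all": defaults.SOC_CATEGORY_SHARES}


def test_zone_los_rule_in_composition():
    assert zone_los(PathwayTiming(), "rule_in") == pytest.approx(2.7)


def test_zone_los_rule_out_includes_alternative_diagnosis_increment():
    timing = PathwayTiming()
    assert timing.alt_dx_increment == pytest.approx(1.3)
    assert zone_los(timing, "rule_out") == pytest.approx(4.0)


def test_zone_los_zero_components():
    timing = PathwayTiming(
        t_second_draw=0.0, t_processing=0.0, soc_mean_los_ami=0.0,
        soc_mean_los_nonami=0.0,
    )
    assert zone_los(timing, "rule_in") == 0.0


def test_zone_los_observation_keeps_soc_stratum_means():
    timing = PathwayTiming()
    assert zone_los(timing, "observation_ami") == pytest.approx(5.33)
    assert zone_los(timing, "observation_nonami") == pytest.approx(6.63)


def test_negative_timing_rejected():
    with pytest.raises(ValueError):
        PathwayTiming(t_processing=-0.5)


def test_weighted_mean_los_algorithm_arm():
    summary = weighted_mean_los(
        ALGO_SHARES, category_los_algorithm(PathwayTiming()), arm="1h"
    )
    assert summary.weighted_mean_hours == pytest.approx(4.34, abs=0.005)


def test_weighted_mean_los_soc_arm_and_reduction():
    algo = weighted_mean_los(ALGO_SHARES, category_los_algorithm(PathwayTiming()))
    soc = weighted_mean_los(SOC_SHARES, category_los_soc(PathwayTiming()))
    assert soc.weighted_mean_hours == pytest.approx(6.46, abs=0.005)
    algo = compare_arms(algo, soc)
    assert algo.reduction_vs_comparator_hours == pytest.approx(2.12, abs=0.005)
    assert round(100 * algo.reduction_vs_comparator_pct) == 33


def test_weighted_mean_invariant_under_common_los():
    shares = {"g": {"TP": 0.2, "FN": 0.3, "TN": 0.4, "FP": 0.1}}
    los = {"g": {c: 5.5 for c in ("TP", "FN", "TN", "FP")}}
    assert weighted_mean_los(shares, los).weighted_mean_hours == pytest.approx(5.5)


def test_weighted_mean_validates_shares_and_arity():
    bad_shares = {"g": {"TP": 0.5, "FN": 0.1, "TN": 0.1, "FP": 0.1}}  # sums to .8
    los = {"g": {c: 1.0 for c in ("TP", "FN", "TN", "FP")}}
    with pytest.raises(ValueError):
        weighted_mean_los(bad_shares, los)
    with pytest.raises(ValueError):
        weighted_mean_los({"g": {"TP": 1.0}}, {"other": {"TP": 1.0}})


def test_reduction_identity_share_weighted_differences():
    """Arm LoS difference equals the sum of share-weighted per-cell
    differences when both arms share one category-share layout."""
    timing = PathwayTiming()
    algo_los = category_los_algorithm(timing)
    soc_like = {
        "rule_in_out": category_los_soc(timing)["all"],
        "observation": category_los_soc(timing)["all"],
    }
    arm = weighted_mean_los(ALGO_SHARES, algo_los)
    comp = weighted_mean_los(ALGO_SHARES, soc_like)
    cellwise = sum(
        ALGO_SHARES[g][c] * (soc_like[g][c] - algo_los[g][c])
        for g in ALGO_SHARES
        for c in ALGO_SHARES[g]
    )
    assert comp.weighted_mean_hours - arm.weighted_mean_hours == pytest.approx(
        cellwise, abs=1e-9
    )


def test_null_effect_limit_equalised_arms_have_equal_weighted_los():
    """If zone stays are forced to the standard-of-care stratum means and
    the decisive zones' accuracy equals standard of care, the two arms
    coincide."""
    timing = PathwayTiming(
        t_second_draw=1.7,
        t_processing=5.33 - 1.7,  # rule-in stay = SoC AMI stay
        t_alt_dx=6.63 - 5.33,  # rule-out stay = SoC non-AMI stay
    )
    cfg = TableModeConfig(timing=timing, share_mode="derived")
    cfg.accuracy["rule_in_out_sens"] = cfg.accuracy["soc_sens"]
    cfg.accuracy["rule_in_out_spec"] = cfg.accuracy["soc_spec"]
    ep = evaluate_table_mode(cfg)
    assert ep["los_reduction_hours"] == pytest.approx(0.0, abs=1e-9)


# ------------------------------------------------------------- resource use


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "item", "period", "time_offset"])


def test_rule_out_truncation_and_stress_test():
    events = _events(
        [
            ("A", "ECG", "during_ED", 0.5),
            ("A", "CT scan", "during_ED", 3.0),
        ]
    )
    out = map_resources(events, pd.Series({"A": "rule_out"}), PathwayTiming())
    items = out["item"].tolist()
    assert "ECG" in items  # before the second draw: kept
    assert "CT scan" not in items  # after the second draw: dropped
    assert items.count(STRESS_TEST) == 1
    assert out.loc[out["item"] == STRESS_TEST, "period"].iloc[0] == "post_ED"


def test_observation_profile_passes_through_unchanged():
    events = _events(
        [
            ("B", "ECG", "during_ED", 0.5),
            ("B", "invasive angiography", "during_ED", 3.0),
            ("B", "CABG", "post_ED", 40.0),
        ]
    )
    out = map_resources(events, pd.Series({"B": "observation"}), PathwayTiming())
    pd.testing.assert_frame_equal(out, events)


def test_all_rule_in_cohort_keeps_procedure_counts_drops_stress_tests(rng):
    """Counting oracle: with every patient ruled in, AMI procedure counts
    survive the mapping (moved post-discharge if late) and no stress test
    appears."""
    rows = []
    for i in range(200):
        pid = f"P{i}"
        rows.append((pid, "ECG", "during_ED", float(rng.uniform(0, 4))))
        if rng.random() < 0.5:
            rows.append(
                (pid, str(rng.choice(AMI_PROCEDURES)), "during_ED", float(rng.uniform(0, 6)))
            )
        if rng.random() < 0.2:
            rows.append((pid, str(rng.choice(AMI_PROCEDURES)), "post_ED", 30.0))
    events = _events(rows)
    zones = pd.Series({f"P{i}": "rule_in" for i in range(200)})
    out = map_resources(events, zones, PathwayTiming())

    def proc_count(df):
        return int(df["item"].isin(AMI_PROCEDURES).sum())

    assert proc_count(out) == proc_count(events)
    assert (out["item"] != STRESS_TEST).all()
    # truncation never increases during-ED counts
    assert (out["period"] == "during_ED").sum() <= (events["period"] == "during_ED").sum()


def test_before_ed_events_kept_for_every_zone():
    events = _events(
        [
            ("A", "ECG", "before_ED", -1.0),
            ("B", "ECG", "before_ED", -0.5),
            ("C", "ECG", "before_ED", -2.0),
        ]
    )
    zones = pd.Series({"A": "rule_in", "B": "rule_out", "C": "observation"})
    out = map_resources(events, zones, PathwayTiming())
    assert (out[out["period"] == "before_ED"].groupby("patient_id").size() == 1).all()


def test_unknown_zone_label_rejected():
    events = _events([("A", "ECG", "during_ED", 0.5)])
    with pytest.raises(ValueError, match="zone"):
        map_resources(events, pd.Series({"A": "limbo"}), PathwayTiming())
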