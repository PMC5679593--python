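"""Costing: event costing, expected per-patient totals, savings."""

import numpy as np
import pandas as pd
import pytest

from triage_econ import defaults
from triage_econ.costing import (
    CostBreakdown,
    PeriodCosts,
    UnitCostTable,
    breakdown_from_cells,
    cost_consequence_table,
    cost_events,
    expected_cost,
    savings,
)

UNIT_COSTS = UnitCostTable(
    country="UK",
    currency="GBP",
    item_costs={
        "blood draw": 5.0,
        "ECG": 30.0,
        "CT scan": 120.0,
        "outpatient stress test": 90.0,
        "alt_dx_inpatient": 800.0,
    },
    ed_bed_hour=50.0,
)


def _profile(rows):
    return pd.DataFrame(rows, columns=["patient_id", "item", "period", "time_offset"])


def test_cost_events_empty_profile_zero_stay():
    pc = cost_events(_profile([]), 0.0, UNIT_COSTS)
    assert pc.total == 0.0


def test_cost_events_blood_draws_plus_bed_hours():
    profile = _profile(
        [("A", "blood draw", "during_ED", 0.0), ("A", "blood draw", "during_ED", 1.7)]
    )
    pc = cost_events(profile, 4.0, UNIT_COSTS)
    assert pc.during_ed == pytest.approx(2 * 5.0 + 4.0 * 50.0)  # 210
    assert pc.total == pytest.approx(210.0)


def test_cost_events_alt_dx_items_booked_to_alt_bucket():
    profile = _profile([("A", "alt_dx_inpatient", "post_ED", 10.0)])
    pc = cost_events(profile, 0.0, UNIT_COSTS)
    assert pc.alt_dx == pytest.approx(800.0)
    assert pc.post_ed == 0.0


def test_cost_events_missing_item_names_it():
    profile = _profile([("A", "MRI scan", "during_ED", 1.0)])
    with pytest.raises(KeyError, match="MRI scan"):
        cost_events(profile, 1.0, UNIT_COSTS)


def test_cost_events_agrees_with_brute_force_summation(rng):
    """Independent oracle: per-event python-loop summation over random
    profiles equals the module's period totals."""
    items = list(UNIT_COSTS.item_costs)
    for _ in range(50):
        n = int(rng.integers(0, 20))
        rows = [
            (
                "X",
                items[int(rng.integers(len(items)))],
                ["before_ED", "during_ED", "post_ED"][int(rng.integers(3))],
                float(rng.uniform(0, 10)),
            )
            for _ in range(n)
        ]
        los = float(rng.uniform(0, 12))
        pc = cost_events(_profile(rows), los, UNIT_COSTS)
        expected = los * UNIT_COSTS.ed_bed_hour
        total = 0.0
        for _, item, period, _t in rows:
            total += UNIT_COSTS.item_costs[item]
        assert pc.total == pytest.approx(total + expected, abs=1e-9)


def test_expected_cost_reproduces_published_uk_totals():
    # 1-h arm: published share-weighted cells summed via unit shares
    algo = breakdown_from_cells("UK", "algorithm")
    assert algo.total == pytest.approx(2480, abs=2)
    soc = breakdown_from_cells("UK", "soc")
    assert soc.total == pytest.approx(4561, abs=2)


def test_expected_cost_share_times_cost_identity():
    costs = {"g": {"TP": 100.0, "FN": 200.0, "TN": 50.0, "FP": 75.0}}
    shares = {"g": {"TP": 0.25, "FN": 0.25, "TN": 0.25, "FP": 0.25}}
    assert expected_cost(costs, shares) == pytest.approx(106.25)
    # single category with share 1 returns its cost
    assert expected_cost(
        {"g": {"TP": 123.0}}, {"g": {"TP": 1.0}}
    ) == pytest.approx(123.0)


def test_expected_cost_validates_shares():
    costs = {"g": {"TP": 1.0}}
    with pytest.raises(ValueError):
        expected_cost(costs, {"g": {"TP": 0.5}})
    with pytest.raises(ValueError):
        expected_cost(costs, {"g": {"TP": 0.5, "FN": 0.5}})


@pytest.mark.parametrize(
    "arm,comp,expected_abs,expected_pct",
    [
        ((2480), (4561), 2081, 46),
        ((1504), (2412), 908, 38),
        ((100.0), (100.0), 0.0, 0),
    ],
)
def test_savings_examples(arm, comp, expected_abs, expected_pct):
    absolute, pct = savings(arm, comp)
    assert absolute == pytest.approx(expected_abs)
    assert pct == expected_pct


def test_savings_rejects_nonpositive_comparator():
    with pytest.raises(ValueError):
        savings(10.0, 0.0)


@pytest.mark.parametrize("country,algo_t,soc_t,pct", [
    ("UK", 2480, 4561, 46),
    ("DE", 1504, 2412, 38),
    ("CH", 8668, 14475, 40),
])
def test_cost_consequence_per_country(country, algo_t, soc_t, pct):
    table = cost_consequence_table(country)
    assert table["algorithm_total"] == pytest.approx(algo_t, abs=2)
    assert table["soc_total"] == pytest.approx(soc_t, abs=2)
    assert table["savings_pct"] == pct


def test_period_cells_reconstruct_subtotals_within_rounding():
    """Summing the per-period cells recovers each published category
    subtotal within printed-rounding slack."""
    for country in defaults.COUNTRIES:
        for arm in ("algorithm", "soc"):
            b = breakdown_from_cells(country, arm)
            for group, cats in b.cells.items():
                for cat, pc in cats.items():
                    assert pc.total == pytest.approx(
                        b.subtotals[group][cat], abs=2
                    ), (country, arm, group, cat)


def test_scaling_unit_costs_scales_absolute_not_percent_savings():
    algo = breakdown_from_cells("UK", "algorithm")
    soc = breakdown_from_cells("UK", "soc")
    a0, p0 = savings(algo.total, soc.total)
    a1, p1 = savings(algo.scaled(1.2).total, soc.scaled(1.2).total)
    assert a1 == pytest.approx(1.2 * a0)
    assert p1 == p0


def test_currency_independence_each_country_standalone():
    totals = {c: cost_consequence_table(c)["algorithm_total"] for c in defaults.COUNTRIES}
    currencies = {c: cost_consequence_table(c)["currency"] for c in defaults.COUNTRIES}
    assert len(set(currencies.values())) == 3
    # deliberately different magnitudes across payers; nothing is shared
    assert totals["CH"] > totals["UK"] > totals["DE"]


def test_negative_unit_costs_rejected():
    with pytest.raises(ValueError):
        UnitCostTable(
            country="UK", currency="GBP", item_costs={"ECG": -1.0}, ed_bed_hour=1.0
        )
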