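"""Confusion statistics, zone-group composition and category shares."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triage_econ.accuracy import (
    brute_force_counts,
    category_shares,
    compose_overall,
    confusion,
    overall_algorithm_accuracy,
)

frac = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _labels(tp, fn, tn, fp):
    pred = ["pos"] * tp + ["neg"] * fn + ["neg"] * tn + ["pos"] * fp
    truth = ["pos"] * (tp + fn) + ["neg"] * (tn + fp)
    return pred, truth


def test_confusion_closed_form_rates():
    s = confusion(*_labels(95, 5, 95, 5))
    assert s.sensitivity == pytest.approx(0.95)
    assert s.specificity == pytest.approx(0.95)
    assert s.ppv == pytest.approx(0.95)
    assert s.npv == pytest.approx(0.95)
    assert s.n == 200


def test_confusion_perfect_prediction():
    s = confusion(*_labels(40, 0, 60, 0))
    assert (s.sensitivity, s.specificity, s.ppv, s.npv) == (1.0, 1.0, 1.0, 1.0)


def test_confusion_matches_brute_force_recount(rng):
    """Module counts equal an independent per-pair recount."""
    for _ in range(20):
        n = int(rng.integers(1, 1000))
        pred = rng.choice(["pos", "neg"], n)
        truth = rng.choice(["pos", "neg"], n)
        s = confusion(pred, truth)
        oracle = brute_force_counts(pred, truth)
        assert (s.tp, s.fn, s.tn, s.fp) == (
            oracle["TP"],
            oracle["FN"],
            oracle["TN"],
            oracle["FP"],
        )


def test_confusion_ci_brackets_point_estimate():
    for method in ("wilson", "clopper-pearson"):
        s = confusion(*_labels(80, 20, 150, 50), ci_method=method)
        for rate_name in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = s.ci[rate_name]
            assert lo <= getattr(s, rate_name) <= hi
            assert 0.0 <= lo < hi <= 1.0


def test_confusion_rejects_bad_labels_and_shapes():
    with pytest.raises(ValueError):
        confusion(["yes"], ["pos"])
    with pytest.raises(ValueError):
        confusion([], [])
    with pytest.raises(ValueError):
        confusion(["pos"], ["pos", "neg"])


def test_compose_overall_identity_and_convexity():
    assert compose_overall({"a": 0.8}, {"a": 1.0}) == pytest.approx(0.8)
    rates = {"a": 0.7, "b": 0.9, "c": 0.95}
    weights = {"a": 0.2, "b": 0.5, "c": 0.3}
    overall = compose_overall(rates, weights)
    assert min(rates.values()) <= overall <= max(rates.values())
    # equal rates are invariant to the weighting
    assert compose_overall({"a": 0.8, "b": 0.8}, {"a": 0.1, "b": 0.9}) == pytest.approx(0.8)


def test_compose_overall_condition_weighting_reproduces_published_arithmetic():
    """Composing zone-group sensitivities with condition-positive weights
    lands near the published weighted sensitivity (which its authors
    computed from unrounded inputs, hence the loose tolerance)."""
    sens = compose_overall(
        {"rule_in_out": 0.95, "observation": 0.69},
        {"rule_in_out": 0.1322 / 0.17, "observation": 0.0378 / 0.17},
    )
    assert sens == pytest.approx(0.895, abs=0.005)


def test_compose_overall_validates_weights():
    with pytest.raises(ValueError):
        compose_overall({"a": 0.5}, {"b": 1.0})
    with pytest.raises(ValueError):
        compose_overall({"a": 0.5, "b": 0.5}, {"a": 0.6, "b": 0.6})


def test_overall_accuracy_weighting_modes_differ():
    summaries = {"g1": (0.95, 0.95), "g2": (0.69, 0.98)}
    cond = overall_algorithm_accuracy(
        summaries,
        zone_positives={"g1": 0.1322, "g2": 0.0378},
        zone_negatives={"g1": 0.6455, "g2": 0.1845},
        weighting="condition",
    )
    pat = overall_algorithm_accuracy(
        summaries,
        zone_positives={"g1": 0.1322, "g2": 0.0378},
        zone_negatives={"g1": 0.6455, "g2": 0.1845},
        zone_patients={"g1": 0.7777, "g2": 0.2223},
        weighting="patients",
    )
    assert cond != pat
    assert cond[0] == pytest.approx(0.892, abs=0.002)


@pytest.mark.parametrize(
    "sens,pos_share,expected_tp",
    [
        (0.95, 0.1322, 0.1256),  # decisive zone group
        (0.69, 0.0378, 0.0261),  # observation zone group
    ],
)
def test_category_shares_reproduce_published_true_positive_cells(
    sens, pos_share, expected_tp
):
    shares = category_shares(sens, 0.95, pos_share, 1.0 - pos_share)
    assert shares.tp == pytest.approx(expected_tp, abs=5e-4)


def test_category_shares_perfect_test_has_no_errors():
    shares = category_shares(1.0, 1.0, 0.3, 0.7)
    assert shares.fn == 0.0 and shares.fp == 0.0
    assert shares.tp == pytest.approx(0.3) and shares.tn == pytest.approx(0.7)


@given(sens=frac, spec=frac, pos=frac)
def test_category_shares_sum_to_group_share(sens, spec, pos):
    neg = 1.0 - pos
    shares = category_shares(sens, spec, pos, neg)
    assert shares.total() == pytest.approx(pos + neg, abs=1e-12)


def test_category_shares_rejects_out_of_range():
    with pytest.raises(ValueError):
        category_shares(1.2, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        category_shares(0.9, 0.9, 0.7, 0.4)  # shares exceed 1
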