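"""Diagnostic accuracy: confusion statistics, zone composition, shares.

The 0/1-h algorithm is evaluated against adjudicated diagnosis in two
zone groups: the decisive rule-in/rule-out group (rule-in treated as a
positive call, rule-out as a negative call) and the observation group,
whose accuracy is assumed equal to ED standard of care.  Overall
algorithm accuracy is a weighted average over zone groups; the weights
can be each group's share of condition-positives/negatives (default) or
its share of patients, because published composites are ambiguous about
the denominator.

Population-level TP/FN/TN/FP shares follow the decision-tree identities
TP = positive_share * sens, FN = positive_share * (1 - sens),
TN = negative_share * spec, FP = negative_share * (1 - spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

POS = "pos"
NEG = "neg"
CATEGORIES = ("TP", "FN", "TN", "FP")

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


def _rate_ci(k: int, n: int, method: str) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method=_CI_METHODS[method])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts, rates and 95% CIs from a 2x2 diagnostic cross-tabulation."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    ci_method: str = "wilson"

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(
    pred: Sequence[str],
    truth: Sequence[str],
    ci_method: str = "wilson",
) -> ConfusionSummary:
    """Cross-tabulate predicted vs true labels (``"pos"``/``"neg"``).

    95% CIs use the Wilson score interval by default; exact
    Clopper–Pearson is available via ``ci_method="clopper-pearson"``.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    bad = (set(pred) | set(truth)) - {POS, NEG}
    if bad:
        raise ValueError(f"labels must be 'pos'/'neg'; got {sorted(bad)!r}")
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    tp = int(np.sum((pred == POS) & (truth == POS)))
    fn = int(np.sum((pred == NEG) & (truth == POS)))
    tn = int(np.sum((pred == NEG) & (truth == NEG)))
    fp = int(np.sum((pred == POS) & (truth == NEG)))

    def rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    summary = ConfusionSummary(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
        ci={
            "sensitivity": _rate_ci(tp, tp + fn, ci_method),
            "specificity": _rate_ci(tn, tn + fp, ci_method),
            "ppv": _rate_ci(tp, tp + fp, ci_method),
            "npv": _rate_ci(tn, tn + fn, ci_method),
        },
        ci_method=ci_method,
    )
    return summary


def compose_overall(
    zone_rates: Mapping[str, float],
    weights: Mapping[str, float],
) -> float:
    """Weighted average of zone-group rates.

    ``weights`` must share keys with ``zone_rates``, be non-negative and
    sum to 1 (within 1e-9).  For an overall sensitivity the weights are
    each group's share of condition-positives; for specificity, of
    condition-negatives; for patient-count weighting, of all patients.
    """
    if set(zone_rates) != set(weights):
        raise ValueError("zone_rates and weights must have identical keys")
    w = np.array([weights[g] for g in zone_rates], dtype=float)
    r = np.array([zone_rates[g] for g in zone_rates], dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum():.6f}")
    return float(w @ r)


@dataclass(frozen=True)
class CategoryShares:
    """Population fractions falling in each diagnostic category.

    Within one zone group of one arm: ``tp + fn + tn + fp`` equals that
    group's share of the population (positives + negatives), not 1.
    """

    tp: float
    fn: float
    tn: float
    fp: float
    zone_group: str = ""

    def total(self) -> float:
        return self.tp + self.fn + self.tn + self.fp

    def as_dict(self) -> dict[str, float]:
        return {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp}


def category_shares(
    sens: float,
    spec: float,
    positive_share: float,
    negative_share: float,
    zone_group: str = "",
) -> CategoryShares:
    """Split a zone group's population share into TP/FN/TN/FP fractions."""
    for name, v in (
        ("sens", sens),
        ("spec", spec),
        ("positive_share", positive_share),
        ("negative_share", negative_share),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if positive_share + negative_share > 1.0 + 1e-12:
        raise ValueError("positive_share + negative_share exceeds 1")
    return CategoryShares(
        tp=positive_share * sens,
        fn=positive_share * (1.0 - sens),
        tn=negative_share * spec,
        fp=negative_share * (1.0 - spec),
        zone_group=zone_group,
    )


def overall_algorithm_accuracy(
    zone_summaries: Mapping[str, tuple[float, float]],
    zone_positives: Mapping[str, float],
    zone_negatives: Mapping[str, float],
    zone_patients: Mapping[str, float] | None = None,
    weighting: str = "condition",
) -> tuple[float, float]:
    """Compose overall (sensitivity, specificity) across zone groups.

    ``zone_summaries`` maps group -> (sens, spec).  With the default
    condition weighting, sensitivity is weighted by each group's share of
    positives and specificity by its share of negatives; ``"patients"``
    weights both by the group's share of patients.
    """
    groups = list(zone_summaries)
    if weighting == "condition":
        wp = _normalise({g: zone_positives[g] for g in groups})
        wn = _normalise({g: zone_negatives[g] for g in groups})
    elif weighting == "patients":
        if zone_patients is None:
            raise ValueError("patient weighting requires zone_patients")
        wp = wn = _normalise({g: zone_patients[g] for g in groups})
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sens = compose_overall({g: zone_summaries[g][0] for g in groups}, wp)
    spec = compose_overall({g: zone_summaries[g][1] for g in groups}, wn)
    return sens, spec


def _normalise(weights: Mapping[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("weights sum to zero")
    return {g: w / total for g, w in weights.items()}


def brute_force_counts(
    pred: Iterable[str], truth: Iterable[str]
) -> dict[str, int]:
    """Plain per-pair recount of the 2x2 table (independent oracle)."""
    counts = {c: 0 for c in CATEGORIES}
    for p, t in zip(pred, truth, strict=True):
        if p == POS and t == POS:
            counts["TP"] += 1
        elif p == NEG and t == POS:
            counts["FN"] += 1
        elif p == NEG and t == NEG:
            counts["TN"] += 1
        elif p == POS and t == NEG:
            counts["FP"] += 1
        else:
            raise ValueError(f"bad label pair ({p!r}, {t!r})")
    return counts
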