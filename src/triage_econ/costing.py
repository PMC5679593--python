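"""Per-patient expected costs per arm, country and diagnostic category.

Two entry points coexist:

* event mode — cost an explicit resource-event profile against a unit
  cost table (bed-hours for the ED stay, per-event costs for tests and
  procedures, misdiagnosis/alternative-diagnosis lump sums);
* table mode — work directly from published share-weighted cost cells
  (population category share x per-patient management cost), so arm
  totals are plain sums of cells and savings follow immediately.

Every country (UK/DE/CH; 2016 GBP/EUR/CHF) is costed standalone: no
value ever crosses a currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import defaults
from .accuracy import CATEGORIES

#: items booked to the alternative-diagnosis bucket regardless of period
ALT_DX_ITEMS = (
    "alt_dx_inpatient",
    "ami_inpatient_readmission",
    "ami_treatment_misdiagnosis",
)

PERIODS = defaults.PERIODS  # before_ed, during_ed, post_ed, alt_dx


@dataclass(frozen=True)
class UnitCostTable:
    """Per-item unit costs for one country (one currency, 2016 prices).

    ``item_costs`` maps every resource item to its per-event cost;
    ``ed_bed_hour`` is applied per hour of ED stay (staff time may be a
    separate item or folded into the bed-hour, site convention).
    ``alt_dx_inpatient`` covers inpatient treatment of the true
    alternative condition (true negatives / false positives);
    ``fn_misdiagnosis`` is the repeat inpatient AMI admission of a missed
    AMI; ``fp_misdiagnosis`` the unnecessary AMI treatment of a false
    positive.
    """

    country: str
    currency: str
    item_costs: Mapping[str, float]
    ed_bed_hour: float
    alt_dx_inpatient: Mapping[str, float] = field(default_factory=dict)
    fn_misdiagnosis: float = 0.0
    fp_misdiagnosis: float = 0.0

    def __post_init__(self) -> None:
        if self.ed_bed_hour < 0 or any(v < 0 for v in self.item_costs.values()):
            raise ValueError("unit costs must be >= 0")

    def item_cost(self, item: str) -> float:
        if item in self.item_costs:
            return self.item_costs[item]
        raise KeyError(f"no unit cost for item {item!r} ({self.country})")


@dataclass(frozen=True)
class PeriodCosts:
    """Cost of one patient (or category) split by care period."""

    before_ed: float = 0.0
    during_ed: float = 0.0
    post_ed: float = 0.0
    alt_dx: float = 0.0

    @property
    def total(self) -> float:
        return self.before_ed + self.during_ed + self.post_ed + self.alt_dx

    def scaled(self, k: float) -> "PeriodCosts":
        return PeriodCosts(
            self.before_ed * k, self.during_ed * k, self.post_ed * k, self.alt_dx * k
        )


def cost_events(
    profile: pd.DataFrame,
    los_hours: float,
    unit_costs: UnitCostTable,
) -> PeriodCosts:
    """Cost a single patient's event profile plus the ED stay itself.

    ``profile`` is the long-format event table (columns ``item``,
    ``period``); the ED stay contributes ``los_hours x bed-hour rate`` to
    the during-ED bucket.  A missing unit cost raises KeyError naming the
    item.
    """
    if los_hours < 0:
        raise ValueError("los_hours must be >= 0")
    buckets = {"before_ED": 0.0, "during_ED": 0.0, "post_ED": 0.0, "alt": 0.0}
    for row in profile.itertuples(index=False):
        cost = unit_costs.item_cost(row.item)
        if row.item in ALT_DX_ITEMS:
            buckets["alt"] += cost
        else:
            if row.period not in ("before_ED", "during_ED", "post_ED"):
                raise ValueError(f"unknown period {row.period!r}")
            buckets[row.period] += cost
    buckets["during_ED"] += los_hours * unit_costs.ed_bed_hour
    return PeriodCosts(
        before_ed=buckets["before_ED"],
        during_ed=buckets["during_ED"],
        post_ed=buckets["post_ED"],
        alt_dx=buckets["alt"],
    )


def expected_cost(
    category_costs: Mapping[str, Mapping[str, float]],
    shares: Mapping[str, Mapping[str, float]],
) -> float:
    """Per-patient expected cost: sum of share x per-patient category cost.

    ``category_costs[group][cat]`` is the cost of managing one patient of
    that category; ``shares`` is the matching population-share layout and
    must sum to 1 over all cells.
    """
    total_share = 0.0
    total = 0.0
    for group, cats in shares.items():
        if group not in category_costs:
            raise ValueError(f"no costs for zone group {group!r}")
        for cat, share in cats.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if cat not in category_costs[group]:
                raise ValueError(f"no cost for ({group!r}, {cat!r})")
            total_share += share
            total += share * category_costs[group][cat]
    if abs(total_share - 1.0) > 1e-6:
        raise ValueError(f"shares must sum to 1, got {total_share:.6f}")
    return total


def savings(arm_total: float, comparator_total: float) -> tuple[float, int]:
    """(absolute, percent) savings of an arm versus its comparator.

    Percent is rounded to the integer percent it is reported at.
    """
    if comparator_total <= 0:
        raise ValueError("comparator total must be positive")
    absolute = comparator_total - arm_total
    pct = int(round(100.0 * absolute / comparator_total))
    return absolute, pct


# ---------------------------------------------------------------------------
# table mode


@dataclass(frozen=True)
class CostBreakdown:
    """Share-weighted cost cells of one arm in one country.

    ``cells`` holds the per-period detail; ``subtotals`` the published
    per-category subtotal cells, which take precedence in totals because
    the per-period cells are rounded independently (their sums can drift
    from the subtotal by a couple of currency units).
    """

    arm: str
    country: str
    currency: str
    cells: Mapping[str, Mapping[str, PeriodCosts]]  # group -> category -> periods
    subtotals: Mapping[str, Mapping[str, float]] | None = None

    def group_category_total(self, group: str, cat: str) -> float:
        if self.subtotals is not None:
            return self.subtotals[group][cat]
        return self.cells[group][cat].total

    @property
    def total(self) -> float:
        return sum(
            self.group_category_total(g, c)
            for g, cats in self.cells.items()
            for c in cats
        )

    def scaled(self, k: float) -> "CostBreakdown":
        return CostBreakdown(
            arm=self.arm,
            country=self.country,
            currency=self.currency,
            cells={
                g: {c: pc.scaled(k) for c, pc in cats.items()}
                for g, cats in self.cells.items()
            },
            subtotals=None
            if self.subtotals is None
            else {
                g: {c: v * k for c, v in cats.items()}
                for g, cats in self.subtotals.items()
            },
        )


def breakdown_from_cells(
    country: str,
    arm: str,
    cells: Mapping | None = None,
) -> CostBreakdown:
    """Build a :class:`CostBreakdown` from published share-weighted cells."""
    source = (cells or defaults.COST_CELLS)[country]
    arm_key = "algorithm" if arm in ("algorithm", "1h") else "soc"
    period_cells: dict[str, dict[str, PeriodCosts]] = {}
    subtotals: dict[str, dict[str, float]] = {}
    for group, cats in source[arm_key].items():
        period_cells[group] = {}
        subtotals[group] = {}
        for cat, cell in cats.items():
            period_cells[group][cat] = PeriodCosts(
                before_ed=float(cell["before_ed"]),
                during_ed=float(cell["during_ed"]),
                post_ed=float(cell["post_ed"]),
                alt_dx=float(cell["alt_dx"]),
            )
            subtotals[group][cat] = float(cell["total"])
    return CostBreakdown(
        arm=arm,
        country=country,
        currency=source["currency"],
        cells=period_cells,
        subtotals=subtotals,
    )


def cost_consequence_table(
    country: str,
    cells: Mapping | None = None,
) -> dict:
    """Arm totals and savings for one country from published cells."""
    algo = breakdown_from_cells(country, "algorithm", cells)
    soc = breakdown_from_cells(country, "soc", cells)
    absolute, pct = savings(algo.total, soc.total)
    return {
        "country": country,
        "currency": algo.currency,
        "algorithm_total": algo.total,
        "soc_total": soc.total,
        "savings_absolute": absolute,
        "savings_pct": pct,
        "algorithm": algo,
        "soc": soc,
    }
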