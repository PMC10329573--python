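"""Laboratory workup cost categories and savings from cultures avoided.

Each culture's laboratory workup falls in one of four price categories:
a negative workup (no significant growth, including mixed contaminants),
a Gram-positive identification workup, a Gram-negative one, or both when a
culture grows organisms of both Gram classes.  The category reflects the
*laboratory* work done, not the adjudicated label: a culture can grow a
low-count contaminant (adjudicated negative) and still incur an
identification workup.

Savings under a screening rule are the workups for the screen-negative
samples — the cultures that would not have been performed.  Currency
arithmetic is exact decimal: each category row is count x unit price rounded
half-up to whole euros, and the total is the sum of the rounded rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Sequence, Union

import pandas as pd

from .cohort_model import (
    CultureObservation,
    GramClass,
    GrowthStatus,
    OrganismCatalog,
    Sample,
    classify_organism,
    default_catalog,
)
from .evaluation import round_half_up
from .exceptions import AdjudicationError, InputError
from .screening import ScreeningRule, parse_rule

__all__ = [
    "WorkupCategory",
    "PriceTable",
    "SavingsBreakdown",
    "cost_category",
    "savings_breakdown",
    "annualize",
    "default_prices",
]


#: Workup category codes, in reporting order.
NEGATIVE_WORKUP = "negative_workup"
GRAM_POSITIVE = "gram_positive"
GRAM_NEGATIVE = "gram_negative"
BOTH = "both"
YEAST = "yeast"

CATEGORY_ORDER = (NEGATIVE_WORKUP, GRAM_POSITIVE, GRAM_NEGATIVE, BOTH, YEAST)

WorkupCategory = str


def _to_price(value) -> Decimal:
    price = value if isinstance(value, Decimal) else Decimal(str(value))
    if not price > 0:
        raise InputError(f"prices must be > 0, got {value!r}")
    return price


@dataclass(frozen=True)
class PriceTable:
    """Unit prices per workup category, in euros.

    ``yeast`` is an optional separate slot; when unset, yeast-only cultures
    are priced as Gram-positive workups.  Prices are stored as exact decimals;
    config files use plain dot-decimal numbers (no locale commas).
    """

    negative_workup: Decimal = Decimal("24.66")
    gram_positive: Decimal = Decimal("68.87")
    gram_negative: Decimal = Decimal("90.11")
    both: Decimal = Decimal("158.98")
    yeast: Decimal | None = None

    def __post_init__(self):
        import warnings

        for name in ("negative_workup", "gram_positive", "gram_negative", "both"):
            object.__setattr__(self, name, _to_price(getattr(self, name)))
        if self.yeast is not None:
            object.__setattr__(self, "yeast", _to_price(self.yeast))
        if self.both < max(self.gram_positive, self.gram_negative):
            warnings.warn(
                "price for 'both' workup is below a single-class workup",
                stacklevel=2,
            )

    def price(self, category: WorkupCategory) -> Decimal:
        if category == YEAST:
            return self.yeast if self.yeast is not None else self.gram_positive
        return getattr(self, category)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PriceTable":
        return cls(**{k: v for k, v in raw.items() if v is not None})


def default_prices() -> PriceTable:
    """The default euro price list for the four workup categories."""
    return PriceTable()


def cost_category(
    culture: CultureObservation,
    catalog: OrganismCatalog | None = None,
    separate_yeast: bool = False,
) -> WorkupCategory:
    """Assign a culture to its laboratory workup category.

    No growth and mixed contaminants take the negative workup; growth takes
    the Gram class of its isolates, or ``both`` when classes are mixed.
    Yeast counts as Gram-positive workup unless ``separate_yeast`` is set.
    """
    if culture.growth_status is not GrowthStatus.GROWTH:
        return NEGATIVE_WORKUP
    catalog = catalog or default_catalog()
    classes = set()
    for iso in culture.isolates:
        entry = classify_organism(iso.organism, catalog)
        if entry.gram_class is GramClass.UNKNOWN:
            raise AdjudicationError(
                f"cannot price growth of unknown organism {iso.organism!r}"
            )
        classes.add(entry.gram_class)
    if separate_yeast and classes == {GramClass.YEAST}:
        return YEAST
    # yeast folds into the Gram-positive identification workup by default
    mapped = {
        GramClass.GRAM_POSITIVE if c is GramClass.YEAST else c for c in classes
    }
    if mapped == {GramClass.GRAM_POSITIVE}:
        return GRAM_POSITIVE
    if mapped == {GramClass.GRAM_NEGATIVE}:
        return GRAM_NEGATIVE
    return BOTH


@dataclass(frozen=True)
class SavingsBreakdown:
    """Counts and rounded euro costs of the cultures a rule avoids."""

    counts: dict[WorkupCategory, int]
    row_costs_eur: dict[WorkupCategory, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total_cost_eur(self) -> int:
        return sum(self.row_costs_eur.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "count": self.counts[cat], "cost_eur": self.row_costs_eur[cat]}
            for cat in CATEGORY_ORDER
            if cat in self.counts
        ]
        rows.append(
            {"category": "total", "count": self.total_count, "cost_eur": self.total_cost_eur}
        )
        return pd.DataFrame(rows, columns=["category", "count", "cost_eur"])


def savings_breakdown(
    samples: Sequence[Sample],
    rule: Union[ScreeningRule, str],
    prices: PriceTable | None = None,
    catalog: OrganismCatalog | None = None,
    separate_yeast: bool = False,
) -> SavingsBreakdown:
    """Cost of the screen-negative cultures, by workup category.

    Row cost = round_half_up(count x unit price) in whole euros; the total is
    the exact sum of the rounded rows.
    """
    if isinstance(rule, str):
        rule = parse_rule(rule)
    prices = prices or default_prices()
    catalog = catalog or default_catalog()
    counts: dict[WorkupCategory, int] = {
        cat: 0 for cat in CATEGORY_ORDER if cat != YEAST or separate_yeast
    }
    for s in samples:
        if s.adjudicated is None:
            raise AdjudicationError(f"sample {s.sample_id} not adjudicated")
        if rule.applies(s.sediment):
            continue
        counts[cost_category(s.culture, catalog, separate_yeast)] += 1
    row_costs = {
        cat: int(round_half_up(Decimal(n) * prices.price(cat), 0))
        for cat, n in counts.items()
    }
    return SavingsBreakdown(counts=counts, row_costs_eur=row_costs)


def annualize(total_eur: Union[int, float, Decimal], months_observed: float) -> int:
    """Linear scaling of an observed-period cost to 12 months, in whole euros."""
    if not months_observed > 0:
        raise InputError(f"months_observed must be > 0, got {months_observed!r}")
    total = total_eur if isinstance(total_eur, Decimal) else Decimal(str(total_eur))
    return int(round_half_up(total * 12 / Decimal(str(months_observed)), 0))
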