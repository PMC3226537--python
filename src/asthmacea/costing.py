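"""Valuation of resource use with unit prices indexed to a target year.

Costs are computed from the healthcare-system perspective.  Items are either
direct medical care (consultations, admissions, diagnostic tests,
medication) or prevention-programme inputs (nurse visits, mite-impermeable
covers, hypoallergenic formula, brochures); intervention items are charged
only to children who received a prevention programme.

Monetary arithmetic is exact decimal internally and rounded half-up to
cents on output.  Index factors are supplied via configuration; the shipped
defaults are identity placeholders, not historical Dutch tariffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, TYPE_CHECKING

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from asthmacea.cohort_prep import ChildRecord

CENT = Decimal("0.01")

DEFAULT_TARGET_YEAR = 2009


class ItemCategory(str, Enum):
    DIRECT_MEDICAL = "direct_medical"
    INTERVENTION = "intervention"


@dataclass(frozen=True)
class PriceEntry:
    unit_price: Decimal
    year: int
    category: ItemCategory

    def __post_init__(self) -> None:
        if self.unit_price < 0:
            raise ValueError(f"unit price must be >= 0, got {self.unit_price}")


@dataclass
class UnitPriceTable:
    """Unit prices with price years, item categories and year-index factors."""

    entries: dict[str, PriceEntry]
    index_factors: dict[int, Decimal] = field(default_factory=dict)
    target_year: int = DEFAULT_TARGET_YEAR

    def __post_init__(self) -> None:
        for year, factor in self.index_factors.items():
            if factor <= 0:
                raise ValueError(f"index factor for year {year} must be > 0, got {factor}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "UnitPriceTable":
        entries = {}
        for item, spec in data["items"].items():
            entries[item] = PriceEntry(
                unit_price=Decimal(str(spec["unit_price"])),
                year=int(spec.get("year", data.get("target_year", DEFAULT_TARGET_YEAR))),
                category=ItemCategory(spec["category"]),
            )
        factors = {
            int(y): Decimal(str(f)) for y, f in data.get("index_factors", {}).items()
        }
        return cls(
            entries=entries,
            index_factors=factors,
            target_year=int(data.get("target_year", DEFAULT_TARGET_YEAR)),
        )

    @classmethod
    def from_yaml(cls, path) -> "UnitPriceTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


class UnknownItemError(KeyError):
    def __init__(self, item: str):
        self.item = item
        super().__init__(f"unknown cost item {item!r}")


class MissingIndexFactorError(KeyError):
    def __init__(self, year: int):
        self.year = year
        super().__init__(f"no index factor configured for price year {year}")


def index_price(price: Decimal, price_year: int, table: UnitPriceTable) -> Decimal:
    """Index a price from its price year to the table's target year.

    Target-year prices are returned unchanged; any other year requires a
    configured factor.
    """
    price = Decimal(price)
    if price_year == table.target_year:
        return price
    try:
        factor = table.index_factors[price_year]
    except KeyError:
        raise MissingIndexFactorError(price_year) from None
    return price * factor


def indexed_unit_price(item: str, table: UnitPriceTable) -> Decimal:
    try:
        entry = table.entries[item]
    except KeyError:
        raise UnknownItemError(item) from None
    return index_price(entry.unit_price, entry.year, table)


def child_cost(
    record: "ChildRecord", table: UnitPriceTable, include_intervention: bool
) -> Decimal:
    """Total cost of one child's resource use, rounded half-up to cents.

    Intervention-category items are counted only when ``include_intervention``
    is true (prevention-arm children); direct medical items always count.
    """
    total = Decimal(0)
    for item, quantity in record.resource_use.items():
        if item not in table.entries:
            raise UnknownItemError(item)
        if quantity < 0:
            raise ValueError(f"negative quantity for item {item!r}: {quantity}")
        entry = table.entries[item]
        if entry.category is ItemCategory.INTERVENTION and not include_intervention:
            continue
        total += Decimal(quantity) * indexed_unit_price(item, table)
    return total.quantize(CENT, rounding=ROUND_HALF_UP)


def default_price_table() -> UnitPriceTable:
    """Placeholder unit prices (target year already; identity indexation).

    These are runnable defaults for synthetic cohorts, not estimates of any
    real tariff schedule.
    """
    direct = ItemCategory.DIRECT_MEDICAL
    interv = ItemCategory.INTERVENTION
    spec = {
        "gp_visit": ("28.00", direct),
        "specialist_visit": ("72.00", direct),
        "hospital_admission": ("400.00", direct),
        "chest_xray": ("45.00", direct),
        "allergen_assay": ("55.00", direct),
        "medication": ("30.00", direct),
        "nurse_visit": ("35.00", interv),
        "mite_cover": ("60.00", interv),
        "formula_feeding": ("80.00", interv),
        "brochure": ("5.00", interv),
    }
    entries = {
        item: PriceEntry(Decimal(price), DEFAULT_TARGET_YEAR, cat)
        for item, (price, cat) in spec.items()
    }
    return UnitPriceTable(entries=entries)
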