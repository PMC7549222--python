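"""Convert medication records to mg of active ingredient and treatable kg.

Two amount formulas drive everything:

* medicated feed:  ``weight of medicated feed (kg) x inclusion rate (mg/kg)``;
* all other products:  ``number of packs x pack size (g or ml) x strength
  (mg per ml or per g)``, then prodrug/I.U. conversion.

Amounts are standardised for potency as *treatable kilograms* (TK): the
kilograms of pig treatable for one day with the given mass at the compound's
defined daily dose, ``TK = mg / DDDvet``.  Long-acting injectables without a
DDDvet use ``TK = mg / la_dose x la_factor`` (one administration covers
``la_factor`` days), which the catalog folds into a single effective daily
dose so one formula serves every ingredient.

Missing pack counts are imputed before quantification: the farmer's own
estimate takes precedence; otherwise the median count over the other farms
using the same product is used.  Imputed records are flagged.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd

from .catalog import ActiveIngredientRef, Catalog, resolve_active_mass
from .errors import DomainError, MissingDoseError, UnimputableError, ValidationError
from .records import (
    AgeCategory,
    FeedMedicationRecord,
    ProductUsageRecord,
    Route,
    allocate_to_age,
)

USAGE_TABLE_COLUMNS = [
    "farm_id",
    "ingredient",
    "antimicrobial_class",
    "route",
    "age_category",
    "diet",
    "amount_mg",
    "tk_kg",
    "prophylactic",
    "imputed",
]


@dataclass(frozen=True)
class UsageRecord:
    """One resolved medication event: ingredient x route x age, in mg and TK."""

    farm_id: str
    ingredient: str
    antimicrobial_class: str
    route: Route
    age_category: AgeCategory
    amount_mg: float
    tk_kg: float
    diet: str | None = None
    prophylactic: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.amount_mg < 0 or self.tk_kg < 0:
            raise ValidationError("amount_mg and tk_kg must be >= 0")
        if (self.amount_mg == 0) != (self.tk_kg == 0):
            raise ValidationError("tk_kg must be 0 exactly when amount_mg is 0")


def amount_from_feed(feed_kg: float, inclusion_rate_mg_per_kg: float) -> float:
    """mg of active ingredient in a batch of medicated feed."""
    if feed_kg < 0 or inclusion_rate_mg_per_kg < 0:
        raise DomainError("feed_kg and inclusion rate must be >= 0")
    return feed_kg * inclusion_rate_mg_per_kg


def amount_from_packs(
    n_packs: float,
    pack_size: float,
    strength_mg_per_unit: float,
    ingredient: ActiveIngredientRef,
    declared_in_iu: bool = False,
) -> float:
    """mg of active ingredient in a number of packs of a presentation.

    The declared amount (packs x pack size x strength) passes through
    prodrug/salt and I.U. conversion to the active moiety.
    """
    if n_packs < 0 or pack_size < 0:
        raise DomainError("n_packs and pack_size must be >= 0")
    if strength_mg_per_unit is None or strength_mg_per_unit <= 0:
        raise ValidationError("strength must be a positive number")
    declared = n_packs * pack_size * strength_mg_per_unit
    return resolve_active_mass(declared, ingredient, declared_in_iu)


def to_treatable_kg(amount_mg: float, ingredient: ActiveIngredientRef) -> float:
    """Treatable kilograms for a mass of active ingredient."""
    if amount_mg < 0:
        raise DomainError("amount_mg must be >= 0")
    dose = ingredient.daily_dose_mg_per_kg
    if dose is None or dose <= 0:  # defensive; catalog invariants forbid this
        raise MissingDoseError(f"{ingredient.name}: no usable dose standard")
    return amount_mg / dose


def impute_missing_usage(
    record: ProductUsageRecord, peer_records: list[ProductUsageRecord]
) -> float:
    """Impute a missing pack count for one record.

    The farmer's estimate takes precedence; failing that, the median pack
    count over *other* farms using the same product (even-count median =
    mean of the two central values).
    """
    if record.n_packs is not None:
        raise ValidationError("record has a pack count; nothing to impute")
    if record.farmer_estimate_packs is not None:
        return float(record.farmer_estimate_packs)
    peers = [
        r.n_packs
        for r in peer_records
        if r.product_name == record.product_name
        and r.farm_id != record.farm_id
        and r.n_packs is not None
    ]
    if not peers:
        raise UnimputableError(
            f"{record.farm_id}/{record.product_name}: no farmer estimate and "
            "no peer farms with a recorded count for this product"
        )
    return float(statistics.median(peers))


def impute_all(
    records: list[ProductUsageRecord],
) -> list[ProductUsageRecord]:
    """Fill every missing pack count; identity on complete data.

    Returns a new list in input order; imputed records are recognisable
    downstream because quantification flags them.
    """
    out: list[ProductUsageRecord] = []
    for rec in records:
        if rec.n_packs is not None:
            out.append(rec)
            continue
        filled = ProductUsageRecord(
            farm_id=rec.farm_id,
            product_name=rec.product_name,
            route=rec.route,
            n_packs=impute_missing_usage(rec, records),
            age_allocation=dict(rec.age_allocation),
            prophylactic=rec.prophylactic,
            farmer_estimate_packs=rec.farmer_estimate_packs,
            true_n_packs=rec.true_n_packs,
        )
        out.append(filled)
    return out


def _was_missing(original: ProductUsageRecord) -> bool:
    return original.n_packs is None


def quantify_usage(
    feed_records: list[FeedMedicationRecord],
    product_records: list[ProductUsageRecord],
    catalog: Catalog,
) -> pd.DataFrame:
    """Run both amount formulas over all records and emit the usage table.

    Combination products are decomposed into one row per constituent
    ingredient; product amounts are then split across age categories by the
    record's allocation fractions (mass conserving).  Output columns are
    :data:`USAGE_TABLE_COLUMNS`; masses in mg, TK in kg, unrounded.
    """
    rows: list[UsageRecord] = []

    for rec in feed_records:
        ing = catalog.ingredient(rec.ingredient)
        mg = amount_from_feed(rec.feed_kg, rec.inclusion_rate_mg_per_kg)
        if mg == 0:
            continue
        rows.append(
            UsageRecord(
                farm_id=rec.farm_id,
                ingredient=ing.name,
                antimicrobial_class=ing.antimicrobial_class,
                route=Route.PREMIX_FEED,
                age_category=rec.age_category,
                diet=rec.diet.value,
                amount_mg=mg,
                tk_kg=to_treatable_kg(mg, ing),
                prophylactic=rec.prophylactic,
                imputed=False,
            )
        )

    imputed_flags = [_was_missing(r) for r in product_records]
    complete = impute_all(product_records)
    for rec, was_imputed in zip(complete, imputed_flags):
        product = catalog.product(rec.product_name)
        for content in product.contents:
            ing = catalog.ingredient(content.ingredient)
            mg = amount_from_packs(
                rec.n_packs,
                product.pack_size,
                content.strength_mg_per_unit,
                ing,
                content.declared_in_iu,
            )
            if mg == 0:
                continue
            for age, share in allocate_to_age(mg, rec.age_allocation).items():
                if share == 0:
                    continue
                rows.append(
                    UsageRecord(
                        farm_id=rec.farm_id,
                        ingredient=ing.name,
                        antimicrobial_class=ing.antimicrobial_class,
                        route=rec.route,
                        age_category=age,
                        diet=None,
                        amount_mg=share,
                        tk_kg=to_treatable_kg(share, ing),
                        prophylactic=rec.prophylactic,
                        imputed=was_imputed,
                    )
                )

    return usage_table(rows)


def usage_table(records: list[UsageRecord]) -> pd.DataFrame:
    """Normalised usage table, one row per :class:`UsageRecord`."""
    if not records:
        return pd.DataFrame(columns=USAGE_TABLE_COLUMNS)
    df = pd.DataFrame(
        {
            "farm_id": [r.farm_id for r in records],
            "ingredient": [r.ingredient for r in records],
            "antimicrobial_class": [r.antimicrobial_class for r in records],
            "route": [r.route.value for r in records],
            "age_category": [r.age_category.value for r in records],
            "diet": [r.diet for r in records],
            "amount_mg": [r.amount_mg for r in records],
            "tk_kg": [r.tk_kg for r in records],
            "prophylactic": [r.prophylactic for r in records],
            "imputed": [r.imputed for r in records],
        }
    )
    return df[USAGE_TABLE_COLUMNS]
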