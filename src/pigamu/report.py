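"""Summary surfaces: class x route breakdown, farm-level medians, diet
pattern sets, restricted-class (EMA category B / WHO HP-CIA) summaries,
national extrapolation, and counterfactual record removal.

All report numbers are pure functions of the usage table and the farm
profiles; internal accumulation is unrounded and any rounding (2 decimals,
matching the print precision of the study tables these mirror) happens only
at output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .catalog import CATEGORY_B_CLASSES, Catalog
from .errors import DomainError, ValidationError
from .indicators import IndicatorConfig, farm_indicators, mg_per_pcu, pcu
from .records import (
    GROWER_DIETS,
    FarmProfile,
    FeedMedicationRecord,
    Route,
)

OVERALL = "overall"
TOTAL = "TOTAL"

_SUMMARY_INDICATORS = [
    "mg_per_pcu",
    "ti200",
    "ti_piglet",
    "ti_weaner",
    "ti_finisher",
    "ti_sow",
]


def class_route_breakdown(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    config: IndicatorConfig | None = None,
) -> pd.DataFrame:
    """Breakdown of consumption by antimicrobial class and route.

    Long-form table with one row per class (plus TOTAL) and route (plus
    overall), and columns:

    * ``ai_pct`` — % of overall consumption by weight of active ingredient;
    * ``tk_pct`` — % of overall consumption in treatable kilograms;
    * ``farms_pct`` — % of farms with at least one record of the
      class x route combination (counted once regardless of volume);
    * ``mg_per_pcu`` — consumption for all farms combined, per kg PCU.

    Values are unrounded; percentage columns sum to 100 per route by
    construction.
    """
    if usage.empty:
        raise ValidationError("cannot build a breakdown from an empty usage table")
    config = config or IndicatorConfig()
    n_farms = len(profiles)
    total_pcu = sum(pcu(p, config) for p in profiles)
    total_mg = float(usage["amount_mg"].sum())
    total_tk = float(usage["tk_kg"].sum())

    routes = [r.value for r in Route]
    rows = []
    for route in [OVERALL, *routes]:
        sub = usage if route == OVERALL else usage[usage["route"] == route]
        by_class_mg = sub.groupby("antimicrobial_class")["amount_mg"].sum()
        by_class_tk = sub.groupby("antimicrobial_class")["tk_kg"].sum()
        farms_by_class = sub.groupby("antimicrobial_class")["farm_id"].nunique()
        for cls in sorted(by_class_mg.index):
            mg = float(by_class_mg[cls])
            tk = float(by_class_tk[cls])
            rows.append(
                {
                    "antimicrobial_class": cls,
                    "route": route,
                    "ai_pct": 100.0 * mg / total_mg if total_mg else 0.0,
                    "tk_pct": 100.0 * tk / total_tk if total_tk else 0.0,
                    "farms_pct": 100.0 * int(farms_by_class[cls]) / n_farms,
                    "mg_per_pcu": mg_per_pcu(mg, total_pcu),
                }
            )
        rows.append(
            {
                "antimicrobial_class": TOTAL,
                "route": route,
                "ai_pct": 100.0 * float(sub["amount_mg"].sum()) / total_mg
                if total_mg
                else 0.0,
                "tk_pct": 100.0 * float(sub["tk_kg"].sum()) / total_tk
                if total_tk
                else 0.0,
                "farms_pct": 100.0 * int(sub["farm_id"].nunique()) / n_farms,
                "mg_per_pcu": mg_per_pcu(float(sub["amount_mg"].sum()), total_pcu),
            }
        )
    return pd.DataFrame(rows)


def round_breakdown(breakdown: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Output rounding only; internal tables stay unrounded."""
    out = breakdown.copy()
    for col in ("ai_pct", "tk_pct", "farms_pct", "mg_per_pcu"):
        out[col] = out[col].round(decimals)
    return out


def farm_level_summary(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    config: IndicatorConfig | None = None,
    catalog: Catalog | None = None,
) -> pd.DataFrame:
    """Median (min-max) of each farm-level indicator, stratified by route.

    Strata: overall, each route, and EMA category B.  Every farm contributes
    to every stratum — a farm with no use in a stratum contributes zeros, so
    strata used by fewer than half the farms report a zero median.
    """
    config = config or IndicatorConfig()
    strata: dict[str, pd.DataFrame] = {OVERALL: usage}
    for route in Route:
        strata[route.value] = usage[usage["route"] == route.value]
    strata["category_b"] = _category_b_slice(usage, catalog)

    rows = []
    for stratum, sub in strata.items():
        per_farm = pd.DataFrame(
            [vars(farm_indicators(sub, p, config)) for p in profiles]
        )
        for indicator in _SUMMARY_INDICATORS:
            vals = per_farm[indicator]
            rows.append(
                {
                    "stratum": stratum,
                    "indicator": indicator,
                    "median": float(vals.median()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PatternSets:
    """Per-farm medicated-diet subsets over the growing-pig diets."""

    per_farm: dict[str, frozenset[str]]
    counts: Counter

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": "+".join(sorted(subset)) if subset else "(none)",
                "n_farms": n,
            }
            for subset, n in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["pattern", "n_farms"])


def diet_pattern_sets(
    feed_records: list[FeedMedicationRecord],
    profiles: list[FarmProfile],
) -> PatternSets:
    """Which growing-pig diets each farm medicates (Venn-set membership).

    A diet counts as medicated if the farm has at least one feed-medication
    record with positive tonnage for it.  Farms with no medicated grower
    diet fall in the empty subset, so subset counts sum to the number of
    farms.
    """
    grower = {d.value for d in GROWER_DIETS}
    per_farm: dict[str, set[str]] = {p.farm_id: set() for p in profiles}
    for rec in feed_records:
        if rec.diet.value in grower and rec.feed_kg > 0:
            per_farm.setdefault(rec.farm_id, set()).add(rec.diet.value)
    frozen = {fid: frozenset(s) for fid, s in per_farm.items()}
    return PatternSets(per_farm=frozen, counts=Counter(frozen.values()))


def _category_b_slice(
    usage: pd.DataFrame, catalog: Catalog | None
) -> pd.DataFrame:
    """Rows whose ingredient is EMA category B.

    Uses the catalog's per-ingredient EMA category when available, else the
    fixed category-B class list (polymyxins, fluoroquinolones, 3rd/4th-gen
    cephalosporins).
    """
    if usage.empty:
        return usage
    if catalog is not None:
        is_b = usage["ingredient"].map(
            lambda name: catalog.ingredient(name).ema_category == "B"
        )
    else:
        is_b = usage["antimicrobial_class"].isin(CATEGORY_B_CLASSES)
    return usage[is_b]


def category_b_summary(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    catalog: Catalog | None = None,
    config: IndicatorConfig | None = None,
) -> dict:
    """Pooled shares and farm counts for EMA category B antimicrobials."""
    config = config or IndicatorConfig()
    sub = _category_b_slice(usage, catalog)
    total_mg = float(usage["amount_mg"].sum()) if not usage.empty else 0.0
    total_tk = float(usage["tk_kg"].sum()) if not usage.empty else 0.0
    b_mg = float(sub["amount_mg"].sum()) if not sub.empty else 0.0
    b_tk = float(sub["tk_kg"].sum()) if not sub.empty else 0.0
    n_farms = len(profiles)
    using = set(sub["farm_id"].unique()) if not sub.empty else set()
    return {
        "ai_pct": 100.0 * b_mg / total_mg if total_mg else 0.0,
        "tk_pct": 100.0 * b_tk / total_tk if total_tk else 0.0,
        "farms_without_use": n_farms - len(using),
        "farms_without_use_pct": 100.0 * (n_farms - len(using)) / n_farms
        if n_farms
        else 0.0,
    }


def hpcia_summary(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    catalog: Catalog,
    config: IndicatorConfig | None = None,
) -> dict:
    """Pooled shares for WHO highest-priority critically important classes."""
    config = config or IndicatorConfig()
    if usage.empty:
        return {"ai_pct": 0.0, "tk_pct": 0.0}
    is_hp = usage["ingredient"].map(
        lambda name: catalog.ingredient(name).who_hpcia
    )
    sub = usage[is_hp]
    total_mg = float(usage["amount_mg"].sum())
    total_tk = float(usage["tk_kg"].sum())
    return {
        "ai_pct": 100.0 * float(sub["amount_mg"].sum()) / total_mg if total_mg else 0.0,
        "tk_pct": 100.0 * float(sub["tk_kg"].sum()) / total_tk if total_tk else 0.0,
    }


def national_extrapolation(
    sample_total_mg: float,
    sample_share_of_national_production: float,
    national_sales_mg: float,
) -> float:
    """Estimated % of national veterinary antimicrobial sales attributable
    to the sector, scaling the sample total up by its production share."""
    if not (0.0 < sample_share_of_national_production <= 1.0):
        raise DomainError("sample share must be in (0, 1]")
    if national_sales_mg <= 0:
        raise DomainError("national sales must be > 0")
    return (
        sample_total_mg / sample_share_of_national_production
    ) / national_sales_mg * 100.0


def counterfactual_removal(
    usage: pd.DataFrame,
    predicate: Callable[[pd.Series], bool],
    profiles: list[FarmProfile],
    config: IndicatorConfig | None = None,
) -> float:
    """Pooled mg/PCU after deleting the records matching ``predicate``.

    The PCU denominator is unchanged: the herd still exists, only the
    matched treatments are counterfactually removed.
    """
    config = config or IndicatorConfig()
    total_pcu = sum(pcu(p, config) for p in profiles)
    if usage.empty:
        return mg_per_pcu(0.0, total_pcu)
    keep = usage[~usage.apply(predicate, axis=1)]
    return mg_per_pcu(float(keep["amount_mg"].sum()), total_pcu)
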