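"""Per-farm input data model and CSV I/O.

A farrow-to-finish farm is described for one calendar year by:

* a :class:`FarmProfile` — the population / production denominators (sow
  inventory, pigs slaughtered, stage durations, standard weights at treatment,
  animals at risk per age category, average standing biomass) and the feed
  tonnage per diet category;
* :class:`FeedMedicationRecord` rows — antimicrobial premix use in medicated
  feed, expressed as an inclusion rate (mg active per kg feed) times the
  tonnage of the medicated diet;
* :class:`ProductUsageRecord` rows — all other oral remedies and injectables,
  expressed as pack counts of marketed presentations, with explicit
  age-category allocation fractions (defaulting to an equal split across the
  declared target stages) and an optional farmer estimate standing in for a
  missing pack count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .catalog import Catalog
from .errors import InputValidationError, ValidationError

_ALLOC_TOL = 1e-9


class AgeCategory(str, Enum):
    PIGLET = "piglet"
    WEANER = "weaner"
    FINISHER = "finisher"
    SOW = "sow"


class DietCategory(str, Enum):
    CREEP = "creep"
    STARTER = "starter"
    LINK = "link"
    WEANER = "weaner"
    FINISHER = "finisher"
    GESTATING_SOW = "gestating_sow"
    LACTATING_SOW = "lactating_sow"


#: Each diet is fed in exactly one production stage.
DIET_TO_AGE: dict[DietCategory, AgeCategory] = {
    DietCategory.CREEP: AgeCategory.PIGLET,
    DietCategory.STARTER: AgeCategory.WEANER,
    DietCategory.LINK: AgeCategory.WEANER,
    DietCategory.WEANER: AgeCategory.WEANER,
    DietCategory.FINISHER: AgeCategory.FINISHER,
    DietCategory.GESTATING_SOW: AgeCategory.SOW,
    DietCategory.LACTATING_SOW: AgeCategory.SOW,
}

#: The growing-pig diets tracked by the diet-pattern (Venn) summary.
GROWER_DIETS = (
    DietCategory.STARTER,
    DietCategory.LINK,
    DietCategory.WEANER,
    DietCategory.FINISHER,
)


class Route(str, Enum):
    PREMIX_FEED = "premix_feed"
    WATER = "water"
    TOP_DRESSING = "top_dressing"
    ORAL_DOSE = "oral_dose"
    INJECTABLE = "injectable"


#: Routes that products (as opposed to feed premixes) are administered by.
PRODUCT_ROUTES = (
    Route.WATER,
    Route.TOP_DRESSING,
    Route.ORAL_DOSE,
    Route.INJECTABLE,
)

#: Documented default standard weights at treatment (kg per animal).
#: Reconstructions in the convention of farm-level treatment-incidence
#: studies; overridable per farm.
DEFAULT_WEIGHTS_AT_TREATMENT: dict[AgeCategory, float] = {
    AgeCategory.PIGLET: 2.0,
    AgeCategory.WEANER: 12.0,
    AgeCategory.FINISHER: 70.0,
    AgeCategory.SOW: 220.0,
}

#: Default stage durations (days): weaning at 28 d, weaner stage 9 weeks,
#: slaughter around 24 weeks of age.
DEFAULT_STAGE_DAYS = {"suckling": 28.0, "weaner": 63.0, "finisher": 77.0}


@dataclass
class FarmProfile:
    """One farm's denominators for one calendar year."""

    farm_id: str
    sows: float
    pigs_slaughtered: float
    suckling_days: float = DEFAULT_STAGE_DAYS["suckling"]
    weaner_days: float = DEFAULT_STAGE_DAYS["weaner"]
    finisher_days: float = DEFAULT_STAGE_DAYS["finisher"]
    weights_at_treatment: dict[AgeCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS_AT_TREATMENT)
    )
    animals_at_risk: dict[AgeCategory, float] = field(default_factory=dict)
    avg_biomass_kg: float = 0.0
    feed_kg_per_diet: dict[DietCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in (
            ("sows", self.sows),
            ("pigs_slaughtered", self.pigs_slaughtered),
            ("suckling_days", self.suckling_days),
            ("weaner_days", self.weaner_days),
            ("finisher_days", self.finisher_days),
            ("avg_biomass_kg", self.avg_biomass_kg),
        ):
            if v < 0:
                raise ValidationError(f"{self.farm_id}: {label} must be >= 0")
        if not self.total_rearing_days > 0:
            raise ValidationError(
                f"{self.farm_id}: total rearing period must be > 0"
            )
        for age, w in self.weights_at_treatment.items():
            if w < 0:
                raise ValidationError(
                    f"{self.farm_id}: weight_at_treatment[{age.value}] < 0"
                )
        for age, n in self.animals_at_risk.items():
            if n < 0:
                raise ValidationError(
                    f"{self.farm_id}: animals_at_risk[{age.value}] < 0"
                )
        for diet, kg in self.feed_kg_per_diet.items():
            if kg < 0:
                raise ValidationError(
                    f"{self.farm_id}: feed_kg[{diet.value}] < 0"
                )

    @property
    def total_rearing_days(self) -> float:
        return self.suckling_days + self.weaner_days + self.finisher_days

    def days_at_risk(self, age: AgeCategory) -> float:
        """Days at risk per animal of an age category (sows: the full year)."""
        return {
            AgeCategory.PIGLET: self.suckling_days,
            AgeCategory.WEANER: self.weaner_days,
            AgeCategory.FINISHER: self.finisher_days,
            AgeCategory.SOW: 365.0,
        }[age]


@dataclass
class FeedMedicationRecord:
    """Premix use in one diet: inclusion rate times medicated tonnage."""

    farm_id: str
    diet: DietCategory
    ingredient: str
    inclusion_rate_mg_per_kg: float
    feed_kg: float
    prophylactic: bool = False

    def __post_init__(self) -> None:
        if not self.inclusion_rate_mg_per_kg > 0:
            raise ValidationError(
                f"{self.farm_id}/{self.ingredient}: inclusion rate must be > 0"
            )
        if self.feed_kg < 0:
            raise ValidationError(
                f"{self.farm_id}/{self.ingredient}: feed_kg must be >= 0"
            )

    @property
    def age_category(self) -> AgeCategory:
        return DIET_TO_AGE[self.diet]


@dataclass
class ProductUsageRecord:
    """Non-premix product use: packs of a presentation, split across stages.

    ``n_packs is None`` encodes a missing count to be imputed; in that case a
    ``farmer_estimate_packs`` may be available.  ``true_n_packs`` is a
    generator-only ground-truth column used by recovery tests and ignored by
    the pipeline.
    """

    farm_id: str
    product_name: str
    route: Route
    n_packs: float | None
    age_allocation: dict[AgeCategory, float]
    prophylactic: bool = False
    farmer_estimate_packs: float | None = None
    true_n_packs: float | None = None

    def __post_init__(self) -> None:
        if self.route == Route.PREMIX_FEED:
            raise ValidationError(
                f"{self.farm_id}/{self.product_name}: premix products enter "
                "through feed-medication records, not pack counts"
            )
        if self.n_packs is not None and self.n_packs < 0:
            raise ValidationError(
                f"{self.farm_id}/{self.product_name}: n_packs must be >= 0"
            )
        total = 0.0
        for age, frac in self.age_allocation.items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"{self.farm_id}/{self.product_name}: allocation fraction "
                    f"for {age.value} outside [0, 1]"
                )
            total += frac
        if abs(total - 1.0) > _ALLOC_TOL:
            raise ValidationError(
                f"{self.farm_id}/{self.product_name}: allocation fractions sum "
                f"to {total!r}, expected 1"
            )


def equal_allocation(ages: list[AgeCategory]) -> dict[AgeCategory, float]:
    """Equal split across declared target stages (the neutral default)."""
    if not ages:
        raise ValidationError("allocation requires at least one age category")
    frac = 1.0 / len(ages)
    return {age: frac for age in ages}


def allocate_to_age(
    total_mg: float, allocation: dict[AgeCategory, float]
) -> dict[AgeCategory, float]:
    """Split a total mass across age categories; mass-conserving."""
    s = sum(allocation.values())
    if abs(s - 1.0) > _ALLOC_TOL:
        raise ValidationError(f"allocation fractions sum to {s!r}, expected 1")
    return {age: total_mg * frac for age, frac in allocation.items()}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

FARM_COLUMNS = (
    ["farm_id", "sows", "pigs_slaughtered"]
    + ["suckling_days", "weaner_days", "finisher_days"]
    + [f"weight_{a.value}_kg" for a in AgeCategory]
    + [f"animals_{a.value}" for a in AgeCategory]
    + ["avg_biomass_kg"]
    + [f"feed_kg_{d.value}" for d in DietCategory]
)

FEED_COLUMNS = [
    "farm_id",
    "diet",
    "ingredient",
    "inclusion_rate_mg_per_kg",
    "feed_kg",
    "prophylactic",
]

USAGE_COLUMNS = [
    "farm_id",
    "product_name",
    "route",
    "n_packs",
    *[f"alloc_{a.value}" for a in AgeCategory],
    "prophylactic",
    "farmer_estimate_packs",
    "true_n_packs",
]


def _na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _bool(value) -> bool:
    return str(value).strip().lower() in {"true", "1", "yes"}


def read_farm_inputs(
    farms_path: Path | str,
    feed_path: Path | str,
    usage_path: Path | str,
    catalog: Catalog | None = None,
) -> tuple[list[FarmProfile], list[FeedMedicationRecord], list[ProductUsageRecord]]:
    """Read and cross-validate the three per-farm input files.

    Row-level failures are collected and reported together (file and line);
    referential integrity is enforced against the farm list and, when a
    catalog is supplied, against its ingredients and products.
    """
    errors: list[str] = []

    def read(path, cols):
        try:
            # exact float parsing keeps read -> write byte-stable
            return pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=cols)

    farms_df = read(farms_path, FARM_COLUMNS)
    feed_df = read(feed_path, FEED_COLUMNS)
    usage_df = read(usage_path, USAGE_COLUMNS)

    profiles: list[FarmProfile] = []
    farm_ids: set[str] = set()
    for idx, row in farms_df.iterrows():
        line = int(idx) + 2
        fid = str(row["farm_id"]).strip()
        if fid in farm_ids:
            errors.append(f"{farms_path}:{line}: duplicate farm_id {fid!r}")
            continue
        try:
            profiles.append(
                FarmProfile(
                    farm_id=fid,
                    sows=float(row["sows"]),
                    pigs_slaughtered=float(row["pigs_slaughtered"]),
                    suckling_days=float(row["suckling_days"]),
                    weaner_days=float(row["weaner_days"]),
                    finisher_days=float(row["finisher_days"]),
                    weights_at_treatment={
                        a: float(row[f"weight_{a.value}_kg"]) for a in AgeCategory
                    },
                    animals_at_risk={
                        a: float(row[f"animals_{a.value}"]) for a in AgeCategory
                    },
                    avg_biomass_kg=float(row["avg_biomass_kg"]),
                    feed_kg_per_diet={
                        d: float(row[f"feed_kg_{d.value}"])
                        for d in DietCategory
                        if not _na(row.get(f"feed_kg_{d.value}"))
                    },
                )
            )
            farm_ids.add(fid)
        except (ValidationError, KeyError, TypeError) as exc:
            errors.append(f"{farms_path}:{line}: {exc}")

    feed_records: list[FeedMedicationRecord] = []
    for idx, row in feed_df.iterrows():
        line = int(idx) + 2
        fid = str(row["farm_id"]).strip()
        if fid not in farm_ids:
            errors.append(
                f"{feed_path}:{line}: record references unknown farm {fid!r}"
            )
            continue
        try:
            rec = FeedMedicationRecord(
                farm_id=fid,
                diet=DietCategory(str(row["diet"]).strip()),
                ingredient=str(row["ingredient"]).strip(),
                inclusion_rate_mg_per_kg=float(row["inclusion_rate_mg_per_kg"]),
                feed_kg=float(row["feed_kg"]),
                prophylactic=_bool(row["prophylactic"]),
            )
            if catalog is not None and rec.ingredient not in catalog.ingredients:
                errors.append(
                    f"{feed_path}:{line}: unknown ingredient {rec.ingredient!r}"
                )
                continue
            feed_records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append(f"{feed_path}:{line}: {exc}")

    usage_records: list[ProductUsageRecord] = []
    for idx, row in usage_df.iterrows():
        line = int(idx) + 2
        fid = str(row["farm_id"]).strip()
        if fid not in farm_ids:
            errors.append(
                f"{usage_path}:{line}: record references unknown farm {fid!r}"
            )
            continue
        try:
            alloc = {
                a: float(row[f"alloc_{a.value}"])
                for a in AgeCategory
                if not _na(row.get(f"alloc_{a.value}"))
                and float(row[f"alloc_{a.value}"]) != 0.0
            }
            rec = ProductUsageRecord(
                farm_id=fid,
                product_name=str(row["product_name"]).strip(),
                route=Route(str(row["route"]).strip()),
                n_packs=None if _na(row["n_packs"]) else float(row["n_packs"]),
                age_allocation=alloc,
                prophylactic=_bool(row["prophylactic"]),
                farmer_estimate_packs=(
                    None
                    if _na(row.get("farmer_estimate_packs"))
                    else float(row["farmer_estimate_packs"])
                ),
                true_n_packs=(
                    None
                    if _na(row.get("true_n_packs"))
                    else float(row["true_n_packs"])
                ),
            )
            if catalog is not None and rec.product_name not in catalog.products:
                errors.append(
                    f"{usage_path}:{line}: unknown product {rec.product_name!r}"
                )
                continue
            usage_records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append(f"{usage_path}:{line}: {exc}")

    if errors:
        raise InputValidationError(errors)
    return profiles, feed_records, usage_records


def write_farm_inputs(
    profiles: list[FarmProfile],
    feed_records: list[FeedMedicationRecord],
    usage_records: list[ProductUsageRecord],
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write the three input CSVs; inverse of :func:`read_farm_inputs`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frows = []
    for p in profiles:
        # floats throughout so write -> read -> write is byte-stable
        row: dict = {
            "farm_id": p.farm_id,
            "sows": float(p.sows),
            "pigs_slaughtered": float(p.pigs_slaughtered),
            "suckling_days": float(p.suckling_days),
            "weaner_days": float(p.weaner_days),
            "finisher_days": float(p.finisher_days),
            "avg_biomass_kg": float(p.avg_biomass_kg),
        }
        for a in AgeCategory:
            row[f"weight_{a.value}_kg"] = float(p.weights_at_treatment.get(a, 0.0))
            row[f"animals_{a.value}"] = float(p.animals_at_risk.get(a, 0.0))
        for d in DietCategory:
            row[f"feed_kg_{d.value}"] = p.feed_kg_per_diet.get(d)
        frows.append(row)
    paths = {"farms": out / "farms.csv"}
    pd.DataFrame(frows, columns=FARM_COLUMNS).to_csv(paths["farms"], index=False)

    pd.DataFrame(
        [
            {
                "farm_id": r.farm_id,
                "diet": r.diet.value,
                "ingredient": r.ingredient,
                "inclusion_rate_mg_per_kg": r.inclusion_rate_mg_per_kg,
                "feed_kg": r.feed_kg,
                "prophylactic": r.prophylactic,
            }
            for r in feed_records
        ],
        columns=FEED_COLUMNS,
    ).to_csv(out / "feed_medication.csv", index=False)
    paths["feed_medication"] = out / "feed_medication.csv"

    urows = []
    for r in usage_records:
        row = {
            "farm_id": r.farm_id,
            "product_name": r.product_name,
            "route": r.route.value,
            "n_packs": r.n_packs,
            "prophylactic": r.prophylactic,
            "farmer_estimate_packs": r.farmer_estimate_packs,
            "true_n_packs": r.true_n_packs,
        }
        for a in AgeCategory:
            row[f"alloc_{a.value}"] = r.age_allocation.get(a)
        urows.append(row)
    pd.DataFrame(urows, columns=USAGE_COLUMNS).to_csv(
        out / "product_usage.csv", index=False
    )
    paths["product_usage"] = out / "product_usage.csv"
    return paths
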