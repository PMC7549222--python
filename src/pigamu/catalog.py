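"""Reference catalog of antimicrobial active ingredients and product presentations.

The catalog carries everything needed to turn a declared product amount into a
standardised quantity of active ingredient and a dose-standardised amount:

* the defined daily dose (DDDvet, mg of active ingredient per kg bodyweight per
  day) or, for long-acting injectables without one, an alternative daily-dose
  standard (``la_dose``) together with a long-acting coverage factor
  (``la_factor``);
* a conversion factor mapping the declared prodrug/salt mass to the mass of the
  active moiety (e.g. procaine benzylpenicillin -> benzylpenicillin);
* an I.U.-per-mg factor for products whose strength is declared in
  international units;
* the antimicrobial class and the EMA category (A-D) / WHO highest-priority
  critically-important (HP-CIA) risk flags used for stewardship summaries.

The shipped fixture catalog (``pigamu/data``) covers the 19 compounds handled
by the pipeline's default synthetic population.  Dose standards that are not
fixed by an authoritative printed value carry ``source=placeholder`` and are
intended to be replaced by the user with the official ESVAC figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import (
    MissingConversionError,
    MissingDoseError,
    UnresolvedReferenceError,
    ValidationError,
)

#: Antimicrobial classes recognised by the pipeline.
CLASSES = (
    "tetracyclines",
    "potentiated_sulphonamides",
    "macrolides",
    "penicillins",
    "aminoglycosides",
    "amphenicols",
    "polymyxins",
    "aminocyclitols",
    "lincosamides",
    "fluoroquinolones",
    "cephalosporins_3_4",
    "pleuromutilins",
)

EMA_CATEGORIES = ("A", "B", "C", "D")

#: EMA category B ("restrict") classes.
CATEGORY_B_CLASSES = frozenset(
    {"polymyxins", "fluoroquinolones", "cephalosporins_3_4"}
)

#: Product dose forms.  ``premix`` products carry inclusion-rate semantics
#: (mg active per kg feed) and enter the pipeline through feed-medication
#: records rather than pack counts.
FORMS = ("premix", "water_soluble", "top_dressing", "oral_dose", "injectable")


@dataclass(frozen=True)
class ActiveIngredientRef:
    """One antimicrobial compound and its dose standard.

    Exactly one of ``dddvet`` and ``la_dose`` must be set: the former for
    ordinary compounds, the latter (with ``la_factor``) for long-acting
    injectables that have no assigned DDDvet.
    """

    name: str
    antimicrobial_class: str
    dddvet: float | None = None
    la_dose: float | None = None
    la_factor: float = 1.0
    conversion_factor: float = 1.0
    iu_per_mg: float | None = None
    ema_category: str = "D"
    who_hpcia: bool = False
    source: str = "placeholder"

    def __post_init__(self) -> None:
        if self.antimicrobial_class not in CLASSES:
            raise ValidationError(
                f"{self.name}: unknown antimicrobial class "
                f"{self.antimicrobial_class!r}"
            )
        if (self.dddvet is None) == (self.la_dose is None):
            raise ValidationError(
                f"{self.name}: exactly one of dddvet / la_dose must be set"
            )
        if self.dddvet is not None and not self.dddvet > 0:
            raise ValidationError(f"{self.name}: dddvet must be > 0")
        if self.la_dose is not None and not self.la_dose > 0:
            raise ValidationError(f"{self.name}: la_dose must be > 0")
        if not self.la_factor >= 1.0:
            raise ValidationError(f"{self.name}: la_factor must be >= 1")
        if not (0.0 < self.conversion_factor <= 1.0):
            raise ValidationError(
                f"{self.name}: conversion_factor must be in (0, 1]"
            )
        if self.iu_per_mg is not None and not self.iu_per_mg > 0:
            raise ValidationError(f"{self.name}: iu_per_mg must be > 0")
        if self.ema_category not in EMA_CATEGORIES:
            raise ValidationError(
                f"{self.name}: ema_category must be one of {EMA_CATEGORIES}"
            )

    @property
    def daily_dose_mg_per_kg(self) -> float:
        """Effective daily dose driving treatable-kilogram standardisation.

        Ordinary compounds use their DDDvet directly.  Long-acting
        injectables use ``la_dose / la_factor``: a single administration of
        ``la_dose`` mg/kg covers ``la_factor`` treatment days, so the same
        one-formula standardisation applies to every ingredient.
        """
        if self.dddvet is not None:
            return self.dddvet
        if self.la_dose is not None:
            return self.la_dose / self.la_factor
        raise MissingDoseError(f"{self.name}: no dose standard")  # pragma: no cover


@dataclass(frozen=True)
class IngredientContent:
    """One ingredient's declared strength within a product presentation."""

    ingredient: str
    strength_mg_per_unit: float  # mg (or I.U.) per ml or per g
    declared_in_iu: bool = False

    def __post_init__(self) -> None:
        if not self.strength_mg_per_unit > 0:
            raise ValidationError(
                f"{self.ingredient}: strength must be > 0"
            )


@dataclass(frozen=True)
class ProductPresentation:
    """A marketed presentation: pack size plus per-ingredient strengths.

    Combination products list several ingredient contents; the pipeline
    decomposes them into one usage record per constituent ingredient.
    """

    name: str
    form: str
    pack_size: float  # g or ml per pack
    contents: tuple[IngredientContent, ...]

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValidationError(f"{self.name}: unknown form {self.form!r}")
        if not self.pack_size > 0:
            raise ValidationError(f"{self.name}: pack_size must be > 0")
        if len(self.contents) == 0:
            raise ValidationError(f"{self.name}: product has no ingredients")


@dataclass
class Catalog:
    """Validated ingredient and product reference data."""

    ingredients: dict[str, ActiveIngredientRef] = field(default_factory=dict)
    products: dict[str, ProductPresentation] = field(default_factory=dict)

    def ingredient(self, name: str) -> ActiveIngredientRef:
        try:
            return self.ingredients[name]
        except KeyError:
            raise UnresolvedReferenceError(
                f"unknown active ingredient {name!r}"
            ) from None

    def product(self, name: str) -> ProductPresentation:
        try:
            return self.products[name]
        except KeyError:
            raise UnresolvedReferenceError(f"unknown product {name!r}") from None


def resolve_active_mass(
    declared_amount: float,
    ingredient: ActiveIngredientRef,
    declared_in_iu: bool = False,
) -> float:
    """Convert a declared amount (mg or I.U.) to mg of active ingredient.

    I.U. declarations are first divided by the ingredient's ``iu_per_mg``;
    the result is then multiplied by the prodrug/salt conversion factor.
    Linear in the declared amount; 0 maps to 0.
    """
    if declared_amount < 0:
        raise ValidationError("declared amount must be >= 0")
    mg = float(declared_amount)
    if declared_in_iu:
        if ingredient.iu_per_mg is None:
            raise MissingConversionError(
                f"{ingredient.name}: amount declared in I.U. but no iu_per_mg "
                "conversion on record"
            )
        mg /= ingredient.iu_per_mg
    return mg * ingredient.conversion_factor


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ING_COLUMNS = [
    "name",
    "antimicrobial_class",
    "dddvet_mg_per_kg",
    "la_dose_mg_per_kg",
    "la_factor",
    "conversion_factor",
    "iu_per_mg",
    "ema_category",
    "who_hpcia",
    "source",
]

_PROD_COLUMNS = [
    "product_name",
    "form",
    "pack_size",
    "ingredient",
    "strength_mg_per_unit",
    "declared_in_iu",
]


def _read_csv(path: Path | str, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _bool(value) -> bool:
    return str(value).strip().lower() in {"true", "1", "yes"}


def load_catalog(
    ingredients_path: Path | str, products_path: Path | str | None = None
) -> Catalog:
    """Load and validate a catalog from delimited files.

    Every product ingredient must resolve to a declared active ingredient;
    duplicate ingredient names and duplicate product/ingredient pairs are
    rejected.  Errors name the offending row (1-based, counting the header).
    """
    ing_df = _read_csv(ingredients_path, _ING_COLUMNS)
    ingredients: dict[str, ActiveIngredientRef] = {}
    for idx, row in ing_df.iterrows():
        line = int(idx) + 2
        name = str(row["name"]).strip()
        if name in ingredients:
            raise ValidationError(
                f"{ingredients_path}:{line}: duplicate ingredient {name!r}"
            )
        try:
            ingredients[name] = ActiveIngredientRef(
                name=name,
                antimicrobial_class=str(row["antimicrobial_class"]).strip(),
                dddvet=_opt(row["dddvet_mg_per_kg"]),
                la_dose=_opt(row["la_dose_mg_per_kg"]),
                la_factor=_opt(row["la_factor"]) or 1.0,
                conversion_factor=_opt(row["conversion_factor"]) or 1.0,
                iu_per_mg=_opt(row["iu_per_mg"]),
                ema_category=str(row["ema_category"]).strip(),
                who_hpcia=_bool(row["who_hpcia"]),
                source=str(row["source"]).strip(),
            )
        except ValidationError as exc:
            raise ValidationError(f"{ingredients_path}:{line}: {exc}") from None

    products: dict[str, ProductPresentation] = {}
    if products_path is not None:
        prod_df = _read_csv(products_path, _PROD_COLUMNS)
        grouped: dict[str, dict] = {}
        for idx, row in prod_df.iterrows():
            line = int(idx) + 2
            pname = str(row["product_name"]).strip()
            ing_name = str(row["ingredient"]).strip()
            if ing_name not in ingredients:
                raise UnresolvedReferenceError(
                    f"{products_path}:{line}: product {pname!r} cites unknown "
                    f"ingredient {ing_name!r}"
                )
            entry = grouped.setdefault(
                pname,
                {
                    "form": str(row["form"]).strip(),
                    "pack_size": float(row["pack_size"]),
                    "contents": [],
                },
            )
            if str(row["form"]).strip() != entry["form"] or float(
                row["pack_size"]
            ) != entry["pack_size"]:
                raise ValidationError(
                    f"{products_path}:{line}: product {pname!r} declared with "
                    "inconsistent form or pack size"
                )
            if any(c.ingredient == ing_name for c in entry["contents"]):
                raise ValidationError(
                    f"{products_path}:{line}: duplicate ingredient {ing_name!r} "
                    f"for product {pname!r}"
                )
            try:
                entry["contents"].append(
                    IngredientContent(
                        ingredient=ing_name,
                        strength_mg_per_unit=float(row["strength_mg_per_unit"]),
                        declared_in_iu=_bool(row["declared_in_iu"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"{products_path}:{line}: {exc}"
                ) from None
        for pname, entry in grouped.items():
            products[pname] = ProductPresentation(
                name=pname,
                form=entry["form"],
                pack_size=entry["pack_size"],
                contents=tuple(entry["contents"]),
            )

    return Catalog(ingredients=ingredients, products=products)


def write_catalog(
    catalog: Catalog,
    ingredients_path: Path | str,
    products_path: Path | str | None = None,
) -> None:
    """Write a catalog back to the delimited schema (round-trip stable)."""
    rows = []
    for ing in catalog.ingredients.values():
        rows.append(
            {
                "name": ing.name,
                "antimicrobial_class": ing.antimicrobial_class,
                "dddvet_mg_per_kg": ing.dddvet,
                "la_dose_mg_per_kg": ing.la_dose,
                "la_factor": ing.la_factor,
                "conversion_factor": ing.conversion_factor,
                "iu_per_mg": ing.iu_per_mg,
                "ema_category": ing.ema_category,
                "who_hpcia": ing.who_hpcia,
                "source": ing.source,
            }
        )
    pd.DataFrame(rows, columns=_ING_COLUMNS).to_csv(ingredients_path, index=False)
    if products_path is not None:
        prows = []
        for prod in catalog.products.values():
            for c in prod.contents:
                prows.append(
                    {
                        "product_name": prod.name,
                        "form": prod.form,
                        "pack_size": prod.pack_size,
                        "ingredient": c.ingredient,
                        "strength_mg_per_unit": c.strength_mg_per_unit,
                        "declared_in_iu": c.declared_in_iu,
                    }
                )
        pd.DataFrame(prows, columns=_PROD_COLUMNS).to_csv(products_path, index=False)


def default_catalog() -> Catalog:
    """Load the fixture catalog shipped with the package."""
    data = resources.files("pigamu") / "data"
    return load_catalog(
        str(data / "ingredients.csv"), str(data / "products.csv")
    )
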