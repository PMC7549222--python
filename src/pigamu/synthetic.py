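"""Synthetic farrow-to-finish farm populations with realistic medication use.

The generator emulates the statistical structure of a 67-farm national
cross-section: right-skewed herd sizes (log-normal, clipped to 110-3000 sows,
median ~528), roughly 23.5 slaughter pigs per sow-year, medicated feed on
most farms concentrated in the post-weaning diets, water/top-dressing/oral
product use at the observed farm prevalences, injectables on every farm
(always including a penicillin), and a class mix led by tetracyclines, then
potentiated sulphonamides, macrolides and penicillins.

Sampling contract: one master seed, an independent substream per farm
(spawned from a ``SeedSequence``), so adding farms never perturbs earlier
farms.  Route, diet and product usages are exact per-farm Bernoulli draws
and feed-ingredient picks are iid draws from the configured weights, so
empirical prevalences and class-mix shares have exact binomial sampling
distributions — the basis of the parameter-recovery tests.

What is *not* modelled: within-year treatment timing, disease dynamics, and
any dependence between routes within a farm (usages are independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .records import (
    AgeCategory,
    DietCategory,
    FarmProfile,
    FeedMedicationRecord,
    ProductUsageRecord,
    Route,
    equal_allocation,
)

# Feed ingredient pick weights: class totals follow the observed rank order
# tetracyclines > potentiated sulphonamides > macrolides > penicillins.
DEFAULT_FEED_INGREDIENT_WEIGHTS: dict[str, float] = {
    "chlortetracycline": 0.50,
    "sulfadiazine": 0.17,
    "trimethoprim": 0.03,
    "tylosin": 0.11,
    "tilmicosin": 0.03,
    "amoxicillin": 0.04,
    "apramycin": 0.04,
    "lincomycin": 0.02,
    "spectinomycin": 0.02,
    "florfenicol": 0.02,
    "tiamulin": 0.02,
}

# Typical premix inclusion rates (mg active per kg feed).
DEFAULT_INCLUSION_RATES: dict[str, float] = {
    "chlortetracycline": 300.0,
    "sulfadiazine": 250.0,
    "trimethoprim": 50.0,
    "tylosin": 200.0,
    "tilmicosin": 200.0,
    "amoxicillin": 300.0,
    "apramycin": 100.0,
    "lincomycin": 44.0,
    "spectinomycin": 44.0,
    "florfenicol": 100.0,
    "tiamulin": 100.0,
}

# Annual feed use per animal produced (growing diets, kg per slaughter pig)
# or per sow (sow diets, kg per sow-year).
DEFAULT_FEED_PER_PIG_KG: dict[DietCategory, float] = {
    DietCategory.CREEP: 0.5,
    DietCategory.STARTER: 5.0,
    DietCategory.LINK: 7.0,
    DietCategory.WEANER: 30.0,
    DietCategory.FINISHER: 180.0,
    DietCategory.GESTATING_SOW: 900.0,
    DietCategory.LACTATING_SOW: 350.0,
}

# Fraction of a diet's annual tonnage that is medicated when the farm
# medicates that diet (routine whole-batch prophylaxis for weaners, partial
# coverage elsewhere).
DEFAULT_MEDICATED_FRACTION: dict[DietCategory, float] = {
    DietCategory.CREEP: 0.8,
    DietCategory.STARTER: 0.6,
    DietCategory.LINK: 0.6,
    DietCategory.WEANER: 1.0,
    DietCategory.FINISHER: 0.2,
    DietCategory.GESTATING_SOW: 0.05,
    DietCategory.LACTATING_SOW: 0.05,
}

# Conditional product-use probabilities given the route is used at all,
# chosen so overall product prevalences sit near the observed ones
# (e.g. injectable fluoroquinolone use on ~84% of farms).
DEFAULT_PRODUCT_USE_P: dict[Route, dict[str, float]] = {
    Route.WATER: {
        "apramycin-soluble-1kg": 0.65,
        "amoxicillin-soluble-1kg": 0.40,
        "tylosin-soluble-1.1kg": 0.30,
        "sulfatrim-soluble-1kg": 0.15,
        "colistin-soluble-1kg": 0.33,
        "lincospectin-soluble-150g": 0.18,
    },
    Route.TOP_DRESSING: {"ctc-topdress-5kg": 1.0},
    Route.ORAL_DOSE: {
        "amoxicillin-oral-paste-100g": 0.80,
        "spectinomycin-oral-100ml": 0.40,
    },
    Route.INJECTABLE: {
        "amoxicillin-la-inj-100ml": 0.75,
        "procaine-penicillin-inj-100ml": 0.45,
        "penstrep-inj-100ml": 0.30,
        "enrofloxacin-inj-100ml": 0.60,
        "marbofloxacin-inj-100ml": 0.60,
        "ceftiofur-inj-100ml": 0.239,
        "tulathromycin-inj-50ml": 0.15,
        "tildipirosin-inj-50ml": 0.08,
        "florfenicol-inj-100ml": 0.104,
        "tiamulin-inj-100ml": 0.015,
        "tylosin-inj-100ml": 0.20,
    },
}

# Mean packs per year per 100 sows.
DEFAULT_PACKS_PER_100_SOWS: dict[str, float] = {
    "apramycin-soluble-1kg": 6.0,
    "amoxicillin-soluble-1kg": 5.0,
    "tylosin-soluble-1.1kg": 4.0,
    "sulfatrim-soluble-1kg": 3.0,
    "colistin-soluble-1kg": 3.0,
    "lincospectin-soluble-150g": 8.0,
    "ctc-topdress-5kg": 2.5,
    "amoxicillin-oral-paste-100g": 3.0,
    "spectinomycin-oral-100ml": 3.0,
    "amoxicillin-la-inj-100ml": 25.0,
    "procaine-penicillin-inj-100ml": 20.0,
    "penstrep-inj-100ml": 15.0,
    "enrofloxacin-inj-100ml": 8.0,
    "marbofloxacin-inj-100ml": 8.0,
    "ceftiofur-inj-100ml": 6.0,
    "tulathromycin-inj-50ml": 3.0,
    "tildipirosin-inj-50ml": 3.0,
    "florfenicol-inj-100ml": 3.0,
    "tiamulin-inj-100ml": 3.0,
    "tylosin-inj-100ml": 5.0,
}

# Target stages per product (equal allocation across them).
DEFAULT_PRODUCT_TARGET_STAGES: dict[str, tuple[AgeCategory, ...]] = {
    "apramycin-soluble-1kg": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "amoxicillin-soluble-1kg": (AgeCategory.WEANER,),
    "tylosin-soluble-1.1kg": (AgeCategory.WEANER, AgeCategory.FINISHER),
    "sulfatrim-soluble-1kg": (AgeCategory.WEANER,),
    "colistin-soluble-1kg": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "lincospectin-soluble-150g": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "ctc-topdress-5kg": (
        AgeCategory.WEANER,
        AgeCategory.FINISHER,
        AgeCategory.SOW,
    ),
    "amoxicillin-oral-paste-100g": (AgeCategory.PIGLET,),
    "spectinomycin-oral-100ml": (AgeCategory.PIGLET,),
    "amoxicillin-la-inj-100ml": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "procaine-penicillin-inj-100ml": (AgeCategory.SOW, AgeCategory.FINISHER),
    "penstrep-inj-100ml": (AgeCategory.SOW,),
    "enrofloxacin-inj-100ml": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "marbofloxacin-inj-100ml": (AgeCategory.PIGLET, AgeCategory.SOW),
    "ceftiofur-inj-100ml": (AgeCategory.PIGLET,),
    "tulathromycin-inj-50ml": (AgeCategory.PIGLET, AgeCategory.WEANER),
    "tildipirosin-inj-50ml": (AgeCategory.WEANER,),
    "florfenicol-inj-100ml": (AgeCategory.WEANER, AgeCategory.FINISHER),
    "tiamulin-inj-100ml": (AgeCategory.FINISHER,),
    "tylosin-inj-100ml": (AgeCategory.FINISHER, AgeCategory.SOW),
}


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic population; defaults are the study's
    observed prevalences where printed, documented reconstructions where not."""

    n_farms: int = 67
    seed: int = 0

    # Herd structure
    herd_median_sows: float = 528.0
    herd_lognorm_sigma: float = 0.55
    herd_min_sows: float = 110.0
    herd_max_sows: float = 3000.0
    slaughter_per_sow_mean: float = 23.5
    slaughter_per_sow_sd: float = 2.0
    suckling_days: float = 28.0
    weaner_days: float = 63.0
    finisher_days: float = 77.0
    sow_weight_kg: float = 220.0
    standing_grower_weight_kg: float = 45.0

    # Per-diet medication prevalences
    p_creep: float = 0.522
    p_starter_link: float = 0.881  # at least one of starter/link medicated
    p_both_given_starter_link: float = 0.70
    p_weaner: float = 0.577
    p_finisher: float = 0.239
    p_sow: float = 0.254

    # Per-route product-usage prevalences
    p_water: float = 0.642
    p_top_dressing: float = 0.239
    p_oral_dose: float = 0.313
    p_injectable: float = 1.0

    # Feed medication structure
    feed_ingredient_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEED_INGREDIENT_WEIGHTS)
    )
    inclusion_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCLUSION_RATES)
    )
    inclusion_rate_sigma: float = 0.25
    p_second_feed_regime: float = 0.30  # second iid ingredient pick per diet
    feed_per_pig_kg: dict[DietCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_FEED_PER_PIG_KG)
    )
    medicated_fraction: dict[DietCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATED_FRACTION)
    )

    # Product structure
    product_use_p: dict[Route, dict[str, float]] = field(
        default_factory=lambda: {r: dict(d) for r, d in DEFAULT_PRODUCT_USE_P.items()}
    )
    packs_per_100_sows: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PACKS_PER_100_SOWS)
    )
    product_target_stages: dict[str, tuple[AgeCategory, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PRODUCT_TARGET_STAGES)
    )

    # Prophylaxis probabilities per route
    p_prophylaxis: dict[Route, float] = field(
        default_factory=lambda: {
            Route.PREMIX_FEED: 0.90,
            Route.WATER: 0.79,
            Route.TOP_DRESSING: 0.50,
            Route.ORAL_DOSE: 0.30,
            Route.INJECTABLE: 0.50,
        }
    )

    # Missing prescription records (5 of 67 farms in the study)
    missing_record_probability: float = 5.0 / 67.0
    p_farmer_estimate: float = 0.60
    estimate_noise_sigma: float = 0.20

    def validate(self) -> None:
        if self.n_farms < 0:
            raise ConfigError("n_farms must be >= 0")
        if self.herd_min_sows > self.herd_max_sows:
            raise ConfigError("herd_min_sows > herd_max_sows")
        probs = {
            "p_creep": self.p_creep,
            "p_starter_link": self.p_starter_link,
            "p_both_given_starter_link": self.p_both_given_starter_link,
            "p_weaner": self.p_weaner,
            "p_finisher": self.p_finisher,
            "p_sow": self.p_sow,
            "p_water": self.p_water,
            "p_top_dressing": self.p_top_dressing,
            "p_oral_dose": self.p_oral_dose,
            "p_injectable": self.p_injectable,
            "missing_record_probability": self.missing_record_probability,
            "p_farmer_estimate": self.p_farmer_estimate,
            "p_second_feed_regime": self.p_second_feed_regime,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if abs(sum(self.feed_ingredient_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("feed_ingredient_weights must sum to 1")

    def route_prevalence(self, route: Route) -> float:
        return {
            Route.WATER: self.p_water,
            Route.TOP_DRESSING: self.p_top_dressing,
            Route.ORAL_DOSE: self.p_oral_dose,
            Route.INJECTABLE: self.p_injectable,
        }[route]


def _farm_profile(cfg: GeneratorConfig, rng: np.random.Generator, fid: str) -> FarmProfile:
    mu = math.log(cfg.herd_median_sows)
    sows = float(
        np.clip(
            rng.lognormal(mu, cfg.herd_lognorm_sigma),
            cfg.herd_min_sows,
            cfg.herd_max_sows,
        )
    )
    sows = round(sows)
    rate = max(5.0, rng.normal(cfg.slaughter_per_sow_mean, cfg.slaughter_per_sow_sd))
    slaughtered = round(sows * rate)
    rearing = cfg.suckling_days + cfg.weaner_days + cfg.finisher_days
    biomass = (
        sows * cfg.sow_weight_kg
        + slaughtered * (rearing / 365.0) * cfg.standing_grower_weight_kg
    )
    feed = {
        diet: kg_per_head
        * (sows if diet.value.endswith("sow") else slaughtered)
        for diet, kg_per_head in cfg.feed_per_pig_kg.items()
    }
    return FarmProfile(
        farm_id=fid,
        sows=sows,
        pigs_slaughtered=slaughtered,
        suckling_days=cfg.suckling_days,
        weaner_days=cfg.weaner_days,
        finisher_days=cfg.finisher_days,
        animals_at_risk={
            AgeCategory.PIGLET: round(slaughtered * 1.08),
            AgeCategory.WEANER: round(slaughtered * 1.04),
            AgeCategory.FINISHER: slaughtered,
            AgeCategory.SOW: sows,
        },
        avg_biomass_kg=biomass,
        feed_kg_per_diet=feed,
    )


def _medicated_diets(cfg: GeneratorConfig, rng: np.random.Generator) -> list[DietCategory]:
    diets: list[DietCategory] = []
    if rng.random() < cfg.p_creep:
        diets.append(DietCategory.CREEP)
    if rng.random() < cfg.p_starter_link:
        u = rng.random()
        both = cfg.p_both_given_starter_link
        if u < both:
            diets += [DietCategory.STARTER, DietCategory.LINK]
        elif u < both + (1.0 - both) / 2.0:
            diets.append(DietCategory.STARTER)
        else:
            diets.append(DietCategory.LINK)
    if rng.random() < cfg.p_weaner:
        diets.append(DietCategory.WEANER)
    if rng.random() < cfg.p_finisher:
        diets.append(DietCategory.FINISHER)
    if rng.random() < cfg.p_sow:
        diets.append(
            DietCategory.GESTATING_SOW
            if rng.random() < 0.5
            else DietCategory.LACTATING_SOW
        )
    return diets


def _feed_records(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    profile: FarmProfile,
) -> list[FeedMedicationRecord]:
    names = list(cfg.feed_ingredient_weights)
    weights = np.array([cfg.feed_ingredient_weights[n] for n in names])
    records = []
    for diet in _medicated_diets(cfg, rng):
        n_regimes = 2 if rng.random() < cfg.p_second_feed_regime else 1
        tonnage = (
            profile.feed_kg_per_diet.get(diet, 0.0)
            * cfg.medicated_fraction.get(diet, 0.0)
            / n_regimes
        )
        for _ in range(n_regimes):
            # iid pick (duplicates allowed: regime changes within the year)
            ing = names[int(rng.choice(len(names), p=weights))]
            rate = cfg.inclusion_rates.get(ing, 100.0) * rng.lognormal(
                0.0, cfg.inclusion_rate_sigma
            )
            records.append(
                FeedMedicationRecord(
                    farm_id=profile.farm_id,
                    diet=diet,
                    ingredient=ing,
                    inclusion_rate_mg_per_kg=rate,
                    feed_kg=tonnage,
                    prophylactic=rng.random()
                    < cfg.p_prophylaxis[Route.PREMIX_FEED],
                )
            )
    return records


_PENICILLIN_INJECTABLES = (
    "amoxicillin-la-inj-100ml",
    "procaine-penicillin-inj-100ml",
    "penstrep-inj-100ml",
)


def _product_records(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    profile: FarmProfile,
) -> list[ProductUsageRecord]:
    records = []
    for route, products in cfg.product_use_p.items():
        if rng.random() >= cfg.route_prevalence(route):
            continue
        used = [p for p in products if rng.random() < products[p]]
        if not used:
            # the route is in use on this farm: force one weighted pick so
            # route prevalence matches the configured Bernoulli exactly
            names = list(products)
            w = np.array([products[n] for n in names])
            used = [names[int(rng.choice(len(names), p=w / w.sum()))]]
        if route == Route.INJECTABLE and not any(
            p in _PENICILLIN_INJECTABLES for p in used
        ):
            used.append(_PENICILLIN_INJECTABLES[0])  # all farms inject penicillins
        for product in used:
            mean = cfg.packs_per_100_sows.get(product, 3.0) * profile.sows / 100.0
            n_packs = float(1 + rng.poisson(mean))
            stages = list(cfg.product_target_stages.get(product, (AgeCategory.WEANER,)))
            records.append(
                ProductUsageRecord(
                    farm_id=profile.farm_id,
                    product_name=product,
                    route=route,
                    n_packs=n_packs,
                    age_allocation=equal_allocation(stages),
                    prophylactic=rng.random() < cfg.p_prophylaxis[route],
                )
            )
    return records


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[list[FarmProfile], list[FeedMedicationRecord], list[ProductUsageRecord]]:
    """Generate a farm population with its medication records.

    Deterministic for a fixed seed; farm *i* is drawn from its own spawned
    substream so changing ``n_farms`` never changes earlier farms.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    profiles: list[FarmProfile] = []
    feed: list[FeedMedicationRecord] = []
    products: list[ProductUsageRecord] = []
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_farms)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        profile = _farm_profile(cfg, rng, f"farm{i + 1:05d}")
        profiles.append(profile)
        feed.extend(_feed_records(cfg, rng, profile))
        products.extend(_product_records(cfg, rng, profile))
    return profiles, feed, products


def inject_missingness(
    records: list[ProductUsageRecord],
    probability: float | None = None,
    seed: int = 0,
    p_farmer_estimate: float = 0.60,
    estimate_noise_sigma: float = 0.20,
) -> list[ProductUsageRecord]:
    """Blank pack counts for a random subset of farms, as incomplete
    prescription records would.

    Selection is at farm level (whole prescription files go missing, not
    single lines).  Affected records keep the truth in ``true_n_packs``;
    a log-normally noised farmer estimate is attached with probability
    ``p_farmer_estimate`` — always, when no other farm uses the product,
    since the record would otherwise be unimputable (the study's
    estimate-or-peer-median rule covered every record).
    """
    if probability is None:
        probability = 5.0 / 67.0
    if not (0.0 <= probability <= 1.0):
        raise ConfigError("probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    farm_ids = sorted({r.farm_id for r in records})
    missing_farms = {fid for fid in farm_ids if rng.random() < probability}
    users_by_product: dict[str, set[str]] = {}
    for r in records:
        users_by_product.setdefault(r.product_name, set()).add(r.farm_id)

    out: list[ProductUsageRecord] = []
    for r in records:
        if r.farm_id not in missing_farms or r.n_packs is None:
            out.append(r)
            continue
        peers = users_by_product[r.product_name] - missing_farms
        has_estimate = rng.random() < p_farmer_estimate or not peers
        estimate = (
            round(max(1.0, r.n_packs * rng.lognormal(0.0, estimate_noise_sigma)))
            if has_estimate
            else None
        )
        out.append(
            ProductUsageRecord(
                farm_id=r.farm_id,
                product_name=r.product_name,
                route=r.route,
                n_packs=None,
                age_allocation=dict(r.age_allocation),
                prophylactic=r.prophylactic,
                farmer_estimate_packs=estimate,
                true_n_packs=r.n_packs,
            )
        )
    return out


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """YAML-serialisable provenance dump of a generator configuration."""
    d = asdict(cfg)
    d["feed_per_pig_kg"] = {k.value: v for k, v in cfg.feed_per_pig_kg.items()}
    d["medicated_fraction"] = {
        k.value: v for k, v in cfg.medicated_fraction.items()
    }
    d["product_use_p"] = {
        r.value: dict(p) for r, p in cfg.product_use_p.items()
    }
    d["product_target_stages"] = {
        k: [a.value for a in v] for k, v in cfg.product_target_stages.items()
    }
    d["p_prophylaxis"] = {r.value: p for r, p in cfg.p_prophylaxis.items()}
    return d
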