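"""Farm-level and pooled antimicrobial-consumption indicators.

* **mg/PCU** — mass of active ingredient over the population correction unit,
  a standard-weight biomass denominator: ``PCU = pigs slaughtered x 65 kg +
  sows x 240 kg`` (standard weights configurable).
* **Treatment incidence (TI)** — per age category, the percentage of animals
  treated with one defined daily dose per day at risk:
  ``TI = mg / (DDDvet x kg at treatment x animals at risk x days at risk)
  x 100``.  Summed over ingredients within a category.
* **TI200** — the growing-pig TIs (piglet, weaner, finisher) combined by
  stage-duration weighting and rescaled to a standard 200-day lifespan.
* **DAPD** — doses per 1000 animals per day, the Danish national indicator:
  ``(TK / standard weight) / (animals present x days) x 1000``.
* **DDDA_NAT** — treatment days per average animal-year, the Dutch national
  indicator: ``TK / average standing biomass``.

The exact national conventions behind DAPD/DDDA_NAT are reconstructions with
every denominator explicit and configurable (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .catalog import Catalog
from .errors import DomainError
from .records import AgeCategory, FarmProfile
from .quantify import USAGE_TABLE_COLUMNS

POOLED = "POOLED"

GROWING_AGES = (AgeCategory.PIGLET, AgeCategory.WEANER, AgeCategory.FINISHER)


@dataclass
class IndicatorConfig:
    """Standardisation constants; defaults follow the ESVAC conventions."""

    pcu_slaughter_pig_kg: float = 65.0
    pcu_sow_kg: float = 240.0
    standard_lifespan_days: float = 200.0
    days_per_year: float = 365.0
    #: Standard pig weight used to express standing biomass as animals
    #: present in the DAPD denominator (cancels out of the farm-level rate).
    dapd_standard_weight_kg: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "IndicatorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class IndicatorSet:
    """Per-farm (or pooled) values of every indicator."""

    scope: str
    total_mg: float
    pcu_kg: float
    mg_per_pcu: float
    tk_kg: float
    ti_piglet: float
    ti_weaner: float
    ti_finisher: float
    ti_sow: float
    ti200: float
    dapd: float
    ddda_nat: float


def pcu(profile: FarmProfile, config: IndicatorConfig | None = None) -> float:
    """Population correction unit (kg) for one farm-year."""
    config = config or IndicatorConfig()
    return (
        profile.pigs_slaughtered * config.pcu_slaughter_pig_kg
        + profile.sows * config.pcu_sow_kg
    )


def mg_per_pcu(amount_mg: float, pcu_kg: float) -> float:
    """Milligrams of active ingredient per kg of PCU."""
    if pcu_kg <= 0:
        raise DomainError("mg/PCU undefined: PCU denominator is zero")
    return amount_mg / pcu_kg


def treatment_incidence(
    amount_mg: float,
    dddvet_mg_per_kg: float,
    weight_at_treatment_kg: float,
    n_at_risk: float,
    days_at_risk: float,
) -> float:
    """TI for one ingredient in one age category (per 100 animals at risk)."""
    if amount_mg == 0:
        return 0.0
    for label, v in (
        ("DDDvet", dddvet_mg_per_kg),
        ("weight at treatment", weight_at_treatment_kg),
        ("animals at risk", n_at_risk),
        ("days at risk", days_at_risk),
    ):
        if v <= 0:
            raise DomainError(f"TI undefined: {label} is zero")
    return (
        amount_mg
        / (dddvet_mg_per_kg * weight_at_treatment_kg * n_at_risk * days_at_risk)
        * 100.0
    )


def ti200(
    ti_piglet: float,
    ti_weaner: float,
    ti_finisher: float,
    suckling_days: float,
    weaner_days: float,
    finisher_days: float,
    standard_lifespan_days: float = 200.0,
) -> float:
    """Standardise the growing-pig TIs to a 200-day rearing lifespan.

    Stage-duration-weighted mean of the three TIs times
    ``standard lifespan / total rearing period`` — i.e. the printed
    two-factor form with total rearing period appearing in both factors.
    """
    total = suckling_days + weaner_days + finisher_days
    if total <= 0:
        raise DomainError("TI200 undefined: total rearing period is zero")
    weighted = (
        ti_piglet * suckling_days
        + ti_weaner * weaner_days
        + ti_finisher * finisher_days
    ) / total
    return weighted * standard_lifespan_days / total


def dapd(
    tk_kg: float,
    weight_per_animal_kg: float,
    avg_animals_present: float,
    days_in_period: float,
    per: float = 1000.0,
) -> float:
    """Doses per ``per`` animals per day (Danish DAPD convention)."""
    if tk_kg == 0:
        return 0.0
    if weight_per_animal_kg <= 0 or avg_animals_present <= 0 or days_in_period <= 0:
        raise DomainError("DAPD undefined: zero denominator")
    return (tk_kg / weight_per_animal_kg) / (avg_animals_present * days_in_period) * per


def ddda_nat(tk_kg: float, avg_biomass_kg: float) -> float:
    """Treatment days per average animal-year (Dutch DDDA_NAT convention)."""
    if tk_kg == 0:
        return 0.0
    if avg_biomass_kg <= 0:
        raise DomainError("DDDA_NAT undefined: zero biomass denominator")
    return tk_kg / avg_biomass_kg


# ---------------------------------------------------------------------------
# Farm-level and pooled aggregation over the usage table
# ---------------------------------------------------------------------------


def _ti_by_age(
    usage: pd.DataFrame, profile: FarmProfile
) -> dict[AgeCategory, float]:
    """TI per age category from TK sums.

    Because ``TK = mg / effective daily dose``, the TI formula reduces to
    ``TK / (weight x animals x days) x 100`` summed over ingredients, which
    also gives long-acting injectables their extended coverage.
    """
    out: dict[AgeCategory, float] = {}
    tk_by_age = usage.groupby("age_category")["tk_kg"].sum()
    for age in AgeCategory:
        tk = float(tk_by_age.get(age.value, 0.0))
        if tk == 0:
            out[age] = 0.0
            continue
        w = profile.weights_at_treatment.get(age, 0.0)
        n = profile.animals_at_risk.get(age, 0.0)
        d = profile.days_at_risk(age)
        for label, v in (
            (f"weight at treatment ({age.value})", w),
            (f"animals at risk ({age.value})", n),
            (f"days at risk ({age.value})", d),
        ):
            if v <= 0:
                raise DomainError(f"TI undefined: {label} is zero")
        out[age] = tk / (w * n * d) * 100.0
    return out


def farm_indicators(
    usage: pd.DataFrame,
    profile: FarmProfile,
    config: IndicatorConfig | None = None,
) -> IndicatorSet:
    """All indicators for one farm from its slice of the usage table."""
    config = config or IndicatorConfig()
    sub = usage[usage["farm_id"] == profile.farm_id]
    total_mg = float(sub["amount_mg"].sum())
    tk = float(sub["tk_kg"].sum())
    pcu_kg = pcu(profile, config)
    tis = _ti_by_age(sub, profile)
    t200 = ti200(
        tis[AgeCategory.PIGLET],
        tis[AgeCategory.WEANER],
        tis[AgeCategory.FINISHER],
        profile.suckling_days,
        profile.weaner_days,
        profile.finisher_days,
        config.standard_lifespan_days,
    )
    if profile.avg_biomass_kg > 0:
        animals = profile.avg_biomass_kg / config.dapd_standard_weight_kg
        farm_dapd = dapd(
            tk, config.dapd_standard_weight_kg, animals, config.days_per_year
        )
        farm_ddda = ddda_nat(tk, profile.avg_biomass_kg)
    else:
        farm_dapd = 0.0 if tk == 0 else float("nan")
        farm_ddda = 0.0 if tk == 0 else float("nan")
    return IndicatorSet(
        scope=profile.farm_id,
        total_mg=total_mg,
        pcu_kg=pcu_kg,
        mg_per_pcu=mg_per_pcu(total_mg, pcu_kg),
        tk_kg=tk,
        ti_piglet=tis[AgeCategory.PIGLET],
        ti_weaner=tis[AgeCategory.WEANER],
        ti_finisher=tis[AgeCategory.FINISHER],
        ti_sow=tis[AgeCategory.SOW],
        ti200=t200,
        dapd=farm_dapd,
        ddda_nat=farm_ddda,
    )


def pooled_indicators(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    config: IndicatorConfig | None = None,
) -> IndicatorSet:
    """Indicators for the combined population (ratio of totals, never a
    mean of farm-level values).

    Pooled TIs divide the summed TK by the summed biomass-time denominator
    (weight x animals x days, added over farms); pooled TI200 uses the
    farm-average stage durations.
    """
    config = config or IndicatorConfig()
    total_mg = float(usage["amount_mg"].sum())
    tk = float(usage["tk_kg"].sum())
    total_pcu = sum(pcu(p, config) for p in profiles)
    tk_by_age = usage.groupby("age_category")["tk_kg"].sum()
    tis: dict[AgeCategory, float] = {}
    for age in AgeCategory:
        tk_age = float(tk_by_age.get(age.value, 0.0))
        denom = sum(
            p.weights_at_treatment.get(age, 0.0)
            * p.animals_at_risk.get(age, 0.0)
            * p.days_at_risk(age)
            for p in profiles
        )
        if tk_age == 0:
            tis[age] = 0.0
        elif denom <= 0:
            raise DomainError(f"pooled TI undefined for {age.value}")
        else:
            tis[age] = tk_age / denom * 100.0
    n = len(profiles)
    mean_days = [
        sum(p.suckling_days for p in profiles) / n,
        sum(p.weaner_days for p in profiles) / n,
        sum(p.finisher_days for p in profiles) / n,
    ]
    t200 = ti200(
        tis[AgeCategory.PIGLET],
        tis[AgeCategory.WEANER],
        tis[AgeCategory.FINISHER],
        *mean_days,
        config.standard_lifespan_days,
    )
    total_biomass = sum(p.avg_biomass_kg for p in profiles)
    if total_biomass > 0:
        animals = total_biomass / config.dapd_standard_weight_kg
        pooled_dapd = dapd(
            tk, config.dapd_standard_weight_kg, animals, config.days_per_year
        )
        pooled_ddda = ddda_nat(tk, total_biomass)
    else:
        pooled_dapd = 0.0 if tk == 0 else float("nan")
        pooled_ddda = 0.0 if tk == 0 else float("nan")
    return IndicatorSet(
        scope=POOLED,
        total_mg=total_mg,
        pcu_kg=total_pcu,
        mg_per_pcu=mg_per_pcu(total_mg, total_pcu),
        tk_kg=tk,
        ti_piglet=tis[AgeCategory.PIGLET],
        ti_weaner=tis[AgeCategory.WEANER],
        ti_finisher=tis[AgeCategory.FINISHER],
        ti_sow=tis[AgeCategory.SOW],
        ti200=t200,
        dapd=pooled_dapd,
        ddda_nat=pooled_ddda,
    )


def compute_indicators(
    usage: pd.DataFrame,
    profiles: list[FarmProfile],
    config: IndicatorConfig | None = None,
) -> pd.DataFrame:
    """One row per farm plus a POOLED row; columns are IndicatorSet fields."""
    if usage.empty:
        usage = pd.DataFrame(columns=USAGE_TABLE_COLUMNS)
    sets = [farm_indicators(usage, p, config) for p in profiles]
    sets.append(pooled_indicators(usage, profiles, config))
    return pd.DataFrame([asdict(s) for s in sets])
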