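import pytest
from hypothesis import HealthCheck, settings

import pigamu as pa
from pigamu.records import AgeCategory, DietCategory, Route

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return pa.default_catalog()


def _profile(farm_id, sows, slaughtered, **kw):
    return pa.FarmProfile(
        farm_id=farm_id,
        sows=sows,
        pigs_slaughtered=slaughtered,
        animals_at_risk={
            AgeCategory.PIGLET: round(slaughtered * 1.08),
            AgeCategory.WEANER: round(slaughtered * 1.04),
            AgeCategory.FINISHER: slaughtered,
            AgeCategory.SOW: sows,
        },
        avg_biomass_kg=sows * 220.0 + slaughtered * (168.0 / 365.0) * 45.0,
        **kw,
    )


@pytest.fixture()
def three_farm_bundle():
    """Hand-built three-farm fixture: the study-median herd plus the two
    herd-size extremes, with one feed and one product record each."""
    profiles = [
        _profile(
            "A",
            528,
            12429,
            feed_kg_per_diet={DietCategory.WEANER: 100_000.0},
        ),
        _profile(
            "B",
            110,
            2600,
            feed_kg_per_diet={DietCategory.STARTER: 5_000.0},
        ),
        _profile(
            "C",
            3000,
            58300,
            feed_kg_per_diet={DietCategory.LINK: 20_000.0},
        ),
    ]
    feed = [
        pa.FeedMedicationRecord(
            "A", DietCategory.WEANER, "chlortetracycline", 300.0, 100_000.0, True
        ),
        pa.FeedMedicationRecord(
            "B", DietCategory.STARTER, "sulfadiazine", 250.0, 5_000.0, True
        ),
        pa.FeedMedicationRecord(
            "C", DietCategory.LINK, "tylosin", 100.0, 20_000.0, False
        ),
    ]
    products = [
        pa.ProductUsageRecord(
            "A",
            "marbofloxacin-inj-100ml",
            Route.INJECTABLE,
            10.0,
            {AgeCategory.PIGLET: 1.0},
        ),
        pa.ProductUsageRecord(
            "B",
            "colistin-soluble-1kg",
            Route.WATER,
            2.0,
            {AgeCategory.PIGLET: 0.5, AgeCategory.WEANER: 0.5},
        ),
        pa.ProductUsageRecord(
            "C",
            "procaine-penicillin-inj-100ml",
            Route.INJECTABLE,
            5.0,
            {AgeCategory.SOW: 1.0},
        ),
    ]
    return profiles, feed, products
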