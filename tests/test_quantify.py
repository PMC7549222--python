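import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pigamu as pa
from pigamu.errors import DomainError, UnimputableError
from pigamu.records import AgeCategory, DietCategory, Route


class TestAmountFromFeed:
    def test_typical_inclusion(self):
        # 1000 kg of feed medicated at 300 mg/kg chlortetracycline
        assert pa.amount_from_feed(1000.0, 300.0) == 300_000.0

    def test_zero_feed(self):
        assert pa.amount_from_feed(0.0, 300.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            pa.amount_from_feed(-1.0, 300.0)

    @given(
        kg=st.integers(0, 500),
        rate=st.floats(0.1, 1000.0, allow_nan=False),
    )
    def test_matches_repeated_addition_oracle(self, kg, rate):
        # summing the rate once per kg of feed
        oracle = sum(rate for _ in range(kg))
        assert pa.amount_from_feed(float(kg), rate) == pytest.approx(
            oracle, rel=1e-9, abs=1e-9
        )


class TestAmountFromPacks:
    def test_direct_product(self, catalog):
        ing = catalog.ingredient("enrofloxacin")  # factor 1
        assert pa.amount_from_packs(2, 100.0, 100.0, ing) == 20_000.0

    def test_zero_packs(self, catalog):
        assert pa.amount_from_packs(0, 100.0, 100.0, catalog.ingredient("tylosin")) == 0.0

    def test_prodrug_two_stage(self, catalog):
        # 1 pack x 100 g x 200 mg/g declared prodrug, factor 0.6
        pen = catalog.ingredient("benzylpenicillin")
        assert pa.amount_from_packs(1, 100.0, 200.0, pen) == pytest.approx(12_000.0)

    def test_missing_strength_rejected(self, catalog):
        with pytest.raises(pa.errors.ValidationError):
            pa.amount_from_packs(1, 100.0, 0.0, catalog.ingredient("tylosin"))


class TestTreatableKilograms:
    def test_marbofloxacin_worked_example(self, catalog):
        assert pa.to_treatable_kg(20.0, catalog.ingredient("marbofloxacin")) == 10.0

    def test_zero(self, catalog):
        assert pa.to_treatable_kg(0.0, catalog.ingredient("marbofloxacin")) == 0.0

    def test_long_acting_rule(self, catalog):
        # la_dose 2.5 mg/kg covering la_factor=5 days: 100 mg -> 200 kg
        tula = catalog.ingredient("tulathromycin")
        assert pa.to_treatable_kg(100.0, tula) == pytest.approx(200.0)

    @given(
        amount=st.floats(0, 1e9, allow_nan=False),
        k=st.floats(0.0, 100.0, allow_nan=False),
    )
    def test_homogeneous_degree_one(self, amount, k, catalog):
        ing = catalog.ingredient("chlortetracycline")
        assert pa.to_treatable_kg(k * amount, ing) == pytest.approx(
            k * pa.to_treatable_kg(amount, ing), rel=1e-9, abs=1e-9
        )


def _rec(farm, n_packs, estimate=None, product="apramycin-soluble-1kg"):
    return pa.ProductUsageRecord(
        farm_id=farm,
        product_name=product,
        route=Route.WATER,
        n_packs=n_packs,
        age_allocation={AgeCategory.WEANER: 1.0},
        farmer_estimate_packs=estimate,
    )


class TestImputation:
    def test_farmer_estimate_takes_precedence(self):
        record = _rec("X", None, estimate=5.0)
        peers = [_rec("A", 1.0), _rec("B", 9.0)]
        assert pa.impute_missing_usage(record, peers) == 5.0

    def test_odd_count_peer_median(self):
        record = _rec("X", None)
        peers = [_rec("A", 2.0), _rec("B", 4.0), _rec("C", 9.0)]
        assert pa.impute_missing_usage(record, peers) == 4.0

    def test_even_count_median_is_mean_of_central_values(self):
        record = _rec("X", None)
        peers = [_rec("A", 2.0), _rec("B", 4.0), _rec("C", 6.0), _rec("D", 100.0)]
        assert pa.impute_missing_usage(record, peers) == 5.0

    def test_own_farm_and_other_products_excluded_from_peers(self):
        record = _rec("X", None)
        peers = [
            _rec("X", 50.0),  # same farm: not a peer
            _rec("A", 3.0, product="colistin-soluble-1kg"),  # other product
            _rec("B", 7.0),
        ]
        assert pa.impute_missing_usage(record, peers) == 7.0

    def test_unimputable_names_product(self):
        record = _rec("X", None)
        with pytest.raises(UnimputableError, match="apramycin-soluble-1kg"):
            pa.impute_missing_usage(record, [])

    def test_identity_on_complete_data(self):
        records = [_rec("A", 3.0), _rec("B", 7.0, estimate=1.0)]
        assert pa.impute_all(records) == records


class TestQuantifyUsage:
    def test_three_farm_bundle_hand_computed(self, three_farm_bundle, catalog):
        _, feed, products = three_farm_bundle
        table = pa.quantify_usage(feed, products, catalog)
        by_farm = table.groupby("farm_id")["amount_mg"].sum()
        # A: 100,000 kg feed x 300 mg/kg + 10 x 100 ml x 100 mg/ml marbofloxacin
        assert by_farm["A"] == pytest.approx(30_000_000.0 + 100_000.0)
        # B: 5,000 kg x 250 mg/kg + 2 x 1 kg packs x 2 MIU/g / 30,000 IU/mg
        assert by_farm["B"] == pytest.approx(1_250_000.0 + 2 * 1000 * 2e6 / 30000)
        # C: 20,000 kg x 100 mg/kg + 5 x 100 ml x 300 mg/ml x 0.6 (prodrug)
        assert by_farm["C"] == pytest.approx(2_000_000.0 + 90_000.0)
        # colistin record is split 50/50 across piglet and weaner
        col = table[table.ingredient == "colistin"]
        assert sorted(col.age_category) == ["piglet", "weaner"]
        assert col.amount_mg.iloc[0] == pytest.approx(col.amount_mg.iloc[1])

    def test_combination_product_decomposed(self, catalog):
        rec = pa.ProductUsageRecord(
            "A",
            "lincospectin-soluble-150g",
            Route.WATER,
            2.0,
            {AgeCategory.WEANER: 1.0},
        )
        table = pa.quantify_usage([], [rec], catalog)
        assert sorted(table.ingredient) == ["lincomycin", "spectinomycin"]
        assert table.amount_mg.tolist() == pytest.approx(
            [2 * 150 * 222.0, 2 * 150 * 444.7]
        )

    def test_tk_and_mg_additive_over_partitions(self, catalog):
        rng = np.random.default_rng(42)
        feed = [
            pa.FeedMedicationRecord(
                f"F{i % 5}",
                DietCategory.WEANER,
                "chlortetracycline",
                float(rng.uniform(50, 500)),
                float(rng.uniform(0, 1e5)),
            )
            for i in range(40)
        ]
        table = pa.quantify_usage(feed, [], catalog)
        # record-by-record summation oracle vs grouped aggregation
        oracle_mg = sum(r.feed_kg * r.inclusion_rate_mg_per_kg for r in feed)
        oracle_tk = sum(
            r.feed_kg * r.inclusion_rate_mg_per_kg / 20.0 for r in feed
        )
        assert table["amount_mg"].sum() == pytest.approx(oracle_mg, rel=1e-12)
        assert table["tk_kg"].sum() == pytest.approx(oracle_tk, rel=1e-12)
        grouped = table.groupby("farm_id")["amount_mg"].sum().sum()
        assert grouped == pytest.approx(table["amount_mg"].sum(), rel=1e-12)

    def test_imputed_rows_are_flagged(self, catalog):
        records = [
            _rec("A", 4.0),
            _rec("B", 8.0),
            _rec("X", None),
        ]
        table = pa.quantify_usage([], records, catalog)
        imputed = table[table.farm_id == "X"]
        assert imputed.imputed.all()
        # peer median of {4, 8} packs = 6 packs x 1000 g x 552 mg/g
        assert imputed.amount_mg.sum() == pytest.approx(6 * 1000 * 552.0)
        assert not table[table.farm_id != "X"].imputed.any()

    def test_empty_inputs_give_empty_table(self, catalog):
        table = pa.quantify_usage([], [], catalog)
        assert table.empty
        assert list(table.columns) == pa.quantify.USAGE_TABLE_COLUMNS
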