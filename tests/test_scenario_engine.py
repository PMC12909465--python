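"""Replacement engine: conservation laws, seeded allocation, totals."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dietshift import (
    ScenarioError, ScenarioSpec, apply_scenario, make_scenario,
    nutrient_totals, replicate_allocation_cv, weighted_mean_intake,
)
from conftest import make_food_table, make_persons, make_records


class TestApplyScenario:
    def test_half_meat_splits_each_record(self, tiny_replacement_world):
        records, table, mapping, _ = tiny_replacement_world
        spec = ScenarioSpec("half_meat", "quantity", 0.5, allocation_seed=1)
        out, events = apply_scenario(records, table, mapping, spec)
        # 100 g meat -> 50 g original retained + 50 g replacement added
        kept = out[(out.food_id == "m1") & (out.day_index == 1)]
        assert kept["amount_g"].iloc[0] == 50.0
        assert events["replaced_g"].iloc[0] == 50.0
        assert events["replacement_g"].iloc[0] == 50.0

    def test_energy_strategy_conserves_kilocalories(self, tiny_replacement_world):
        records, table, mapping, _ = tiny_replacement_world
        # restrict candidates to the half-energy-density food
        spec = ScenarioSpec("no_meat", "energy", 1.0, allocation_seed=1)
        out, events = apply_scenario(records, table, {"meat_1": ["a1"]}, spec)
        # 100 g at 2.5 kcal/g -> 200 g at 1.25 kcal/g (250 kcal conserved)
        assert events["replacement_g"].iloc[0] == pytest.approx(200.0, rel=1e-12)
        energy_before = (records.merge(table, left_on="food_id", right_index=True)
                         .eval("amount_g * energy_kcal / 100").sum())
        energy_after = (out.merge(table, left_on="food_id", right_index=True)
                        .eval("amount_g * energy_kcal / 100").sum())
        assert energy_after == pytest.approx(energy_before, rel=1e-9)

    def test_reference_is_identity(self, tiny_replacement_world):
        records, table, mapping, _ = tiny_replacement_world
        out, events = apply_scenario(records, table, mapping,
                                     make_scenario("reference"))
        pd.testing.assert_frame_equal(out, records)
        assert len(events) == 0

    def test_quantity_strategy_conserves_grams(self, small_dataset):
        spec = make_scenario("no_meat", "quantity", master_seed=1)
        out, events = apply_scenario(small_dataset.records, small_dataset.food_table,
                                     small_dataset.mapping, spec)
        assert events["replaced_g"].to_numpy() == pytest.approx(
            events["replacement_g"].to_numpy())
        assert out["amount_g"].sum() == pytest.approx(
            small_dataset.records["amount_g"].sum(), rel=1e-12)

    def test_energy_invariant_under_full_replacement(self, small_dataset):
        spec = make_scenario("no_meat_and_dairy", "energy", master_seed=1)
        out, _ = apply_scenario(small_dataset.records, small_dataset.food_table,
                                small_dataset.mapping, spec)
        table = small_dataset.food_table
        before = (small_dataset.records.merge(table, left_on="food_id", right_index=True)
                  .eval("amount_g * energy_kcal / 100").sum())
        after = (out.merge(table, left_on="food_id", right_index=True)
                 .eval("amount_g * energy_kcal / 100").sum())
        assert after == pytest.approx(before, rel=1e-9)

    def test_half_meat_leaves_exactly_half_the_meat_grams(self, small_dataset):
        table = small_dataset.food_table
        meat_ids = table.index[table["consumed_group"].str.startswith("meat")]
        before = small_dataset.records[
            small_dataset.records.food_id.isin(meat_ids)]["amount_g"].sum()
        spec = make_scenario("half_meat", "quantity", master_seed=1)
        out, _ = apply_scenario(small_dataset.records, table,
                                small_dataset.mapping, spec)
        after = out[out.food_id.isin(meat_ids)]["amount_g"].sum()
        assert after == pytest.approx(0.5 * before, rel=1e-12)

    def test_non_targeted_records_bit_identical(self, small_dataset):
        spec = make_scenario("no_meat", "quantity", master_seed=1)
        out, _ = apply_scenario(small_dataset.records, small_dataset.food_table,
                                small_dataset.mapping, spec)
        table = small_dataset.food_table
        meat_ids = set(table.index[table["consumed_group"].str.startswith("meat")])
        alt_ids = {f for foods in small_dataset.mapping.values() for f in foods}
        keep = ~small_dataset.records.food_id.isin(meat_ids)
        untouched_in = small_dataset.records[keep].reset_index(drop=True)
        untouched_out = out[~out.food_id.isin(alt_ids)].reset_index(drop=True)
        pd.testing.assert_frame_equal(untouched_in, untouched_out)

    def test_no_red_meat_targets_only_red_records(self, small_dataset):
        table = small_dataset.food_table
        spec = make_scenario("no_red_meat", "quantity", master_seed=1)
        out, events = apply_scenario(small_dataset.records, table,
                                     small_dataset.mapping, spec)
        assert table.loc[events["original_food_id"], "is_red_meat"].all()
        nonred_meat = table.index[table["consumed_group"].str.startswith("meat")
                                  & ~table["is_red_meat"]]
        before = small_dataset.records[
            small_dataset.records.food_id.isin(nonred_meat)]["amount_g"].sum()
        after = out[out.food_id.isin(nonred_meat)]["amount_g"].sum()
        assert after == before

    def test_determinism_and_seed_sensitivity(self, small_dataset):
        spec = make_scenario("no_meat", "quantity", master_seed=1)
        out1, ev1 = apply_scenario(small_dataset.records, small_dataset.food_table,
                                   small_dataset.mapping, spec)
        out2, ev2 = apply_scenario(small_dataset.records, small_dataset.food_table,
                                   small_dataset.mapping, spec)
        pd.testing.assert_frame_equal(out1, out2)
        other = ScenarioSpec("no_meat", "quantity", 1.0,
                             allocation_seed=spec.allocation_seed + 1)
        _, ev3 = apply_scenario(small_dataset.records, small_dataset.food_table,
                                small_dataset.mapping, other)
        # same records replaced, only the drawn replacement foods differ
        assert ev1["record_index"].tolist() == ev3["record_index"].tolist()
        assert ev1["replaced_g"].tolist() == ev3["replaced_g"].tolist()
        assert (ev1["replacement_food_id"] != ev3["replacement_food_id"]).any()

    def test_missing_mapping_is_an_error(self, tiny_replacement_world):
        records, table, _, _ = tiny_replacement_world
        with pytest.raises(ScenarioError, match="meat_1"):
            apply_scenario(records, table, {}, ScenarioSpec("no_meat"))

    def test_energy_guard_rejects_caloric_voids(self, tiny_replacement_world):
        records, table, _, _ = tiny_replacement_world
        table = table.copy()
        table.loc["a1", "energy_kcal"] = 1.0  # 0.01 kcal/g: below the guard
        with pytest.raises(ScenarioError, match="energy density"):
            apply_scenario(records, table, {"meat_1": ["a1"]},
                           ScenarioSpec("no_meat", "energy"))


class TestMonotonePlantProteinShare:
    def test_share_increases_with_replacement_extent(self, small_dataset):
        shares = {}
        for name in ("reference", "half_meat", "no_meat", "no_meat_and_dairy"):
            spec = make_scenario(name, "quantity", master_seed=2)
            out, _ = apply_scenario(small_dataset.records, small_dataset.food_table,
                                    small_dataset.mapping, spec)
            totals = nutrient_totals(out, small_dataset.food_table)
            mean = weighted_mean_intake(totals, small_dataset.persons)
            shares[name] = mean["plant_protein_g"] / mean["total_protein_g"]
        assert (shares["reference"] <= shares["half_meat"]
                <= shares["no_meat"] <= shares["no_meat_and_dairy"])


class TestEnumerationOracle:
    def test_seeded_outcome_lies_in_enumerated_allocation_set(
            self, tiny_replacement_world):
        records, table, mapping, persons = tiny_replacement_world
        candidates = mapping["meat_1"]
        enumerated = set()
        for assign in itertools.product(candidates, repeat=len(records)):
            total = 0.0
            for (_, rec), cand in zip(records.iterrows(), assign):
                total += rec.amount_g * table.loc[cand, "total_protein_g"] / 100.0
            enumerated.add(round(total, 9))
        spec = ScenarioSpec("no_meat", "quantity", 1.0, allocation_seed=123)
        out, _ = apply_scenario(records, table, mapping, spec)
        totals = nutrient_totals(out, table)
        seeded = round(float(totals["total_protein_g"].sum()), 9)
        assert seeded in enumerated
        assert min(enumerated) <= seeded <= max(enumerated)


class TestNutrientTotals:
    def test_linearity(self):
        table = make_food_table({"f1": {"plant_protein_g": 3.0}})
        records = make_records([("p1", 1, "f1", 200.0)])
        totals = nutrient_totals(records, table)
        assert totals.loc[("p1", 1), "total_protein_g"] == pytest.approx(6.0)

    def test_additivity_of_duplicate_records(self):
        table = make_food_table({"f1": {"plant_protein_g": 3.0}})
        records = make_records([("p1", 1, "f1", 100.0), ("p1", 1, "f1", 100.0)])
        totals = nutrient_totals(records, table)
        assert totals.loc[("p1", 1), "total_protein_g"] == pytest.approx(6.0)

    def test_empty_day_gives_zero_vector(self):
        table = make_food_table({"f1": {"plant_protein_g": 3.0}})
        records = make_records([("p1", 1, "f1", 100.0)])
        persons = make_persons([("p1", "female", 30, 1.0)])
        totals = nutrient_totals(records, table, persons=persons)
        assert (totals.loc[("p1", 2)] == 0).all()


class TestAllocationCV:
    def test_single_candidate_means_zero_cv(self, tiny_replacement_world):
        records, table, _, persons = tiny_replacement_world
        spec = ScenarioSpec("no_meat", "quantity", 1.0, allocation_seed=7)
        cv = replicate_allocation_cv(records, table, {"meat_1": ["a1"]}, spec,
                                     n_replicates=5, persons=persons)
        assert cv["total_protein_g"] == 0.0

    def test_zero_mean_outcome_is_nan(self, tiny_replacement_world):
        records, table, mapping, persons = tiny_replacement_world
        spec = ScenarioSpec("no_meat", "quantity", 1.0, allocation_seed=7)
        cv = replicate_allocation_cv(records, table, mapping, spec,
                                     n_replicates=3, persons=persons)
        assert np.isnan(cv["vitB12_ug"])  # no B12 anywhere in this tiny world

    def test_requires_at_least_two_replicates(self, tiny_replacement_world):
        records, table, mapping, persons = tiny_replacement_world
        with pytest.raises(ScenarioError):
            replicate_allocation_cv(records, table, mapping,
                                    ScenarioSpec("no_meat"), n_replicates=1,
                                    persons=persons)
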