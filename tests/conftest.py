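"""Shared fixtures: hand-built micro datasets and module-scoped synthetic
surveys (generated programmatically at test time)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dietshift import NUTRIENTS, FOOTPRINTS, SyntheticSpec, generate


def make_food_table(rows: dict[str, dict]) -> pd.DataFrame:
    """Build a food table from {food_id: {column: value}} with zero-filled
    nutrient defaults and a consistent protein split."""
    out = []
    for fid, spec in rows.items():
        row = {"food_id": fid, "name": fid, "consumed_group": "other",
               "is_red_meat": False}
        row.update({n: 0.0 for n in NUTRIENTS})
        row.update({f: 0.0 for f in FOOTPRINTS})
        row.update(spec)
        row["total_protein_g"] = row["plant_protein_g"] + row["animal_protein_g"]
        out.append(row)
    return pd.DataFrame(out).set_index("food_id")


def make_records(rows: list[tuple[str, int, str, float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["person_id", "day_index", "food_id", "amount_g"])


def make_persons(rows: list[tuple[str, str, int, float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["person_id", "sex", "age", "weight_factor"])


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-sex survey for engine-level and pipeline tests."""
    return generate(SyntheticSpec(n_women=60, n_men=60, master_seed=11))


@pytest.fixture(scope="session")
def women_1000():
    """Correctly specified synthetic survey at n = 1000 (one sex) for
    parameter-recovery and cut-point fidelity checks."""
    return generate(SyntheticSpec(n_women=1000, n_men=0, master_seed=5))


@pytest.fixture()
def tiny_replacement_world():
    """Two meat records, three all-plant candidates with distinct protein
    densities: small enough to enumerate every possible allocation."""
    food_table = make_food_table({
        "m1": {"consumed_group": "meat_1", "energy_kcal": 250.0,
               "animal_protein_g": 20.0, "ghg_kgco2eq_per_kg": 10.0},
        "a1": {"energy_kcal": 125.0, "plant_protein_g": 10.0,
               "ghg_kgco2eq_per_kg": 2.0},
        "a2": {"energy_kcal": 200.0, "plant_protein_g": 15.0,
               "ghg_kgco2eq_per_kg": 1.0},
        "a3": {"energy_kcal": 500.0, "plant_protein_g": 30.0,
               "ghg_kgco2eq_per_kg": 3.0},
    })
    records = make_records([("p1", 1, "m1", 100.0), ("p1", 2, "m1", 50.0)])
    persons = make_persons([("p1", "female", 30, 1.0)])
    mapping = {"meat_1": ["a1", "a2", "a3"]}
    return records, food_table, mapping, persons
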