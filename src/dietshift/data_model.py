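"""Core domain types and CSV readers/writers shared by all pipeline stages.

Units are fixed at the boundaries and never converted at parse time:
food composition is per 100 g, environmental footprint factors are per kg,
and consumption amounts are grams. All files are UTF-8 CSV with a "."
decimal separator; numeric columns must not contain missing values (an
explicit 0 is required instead).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The tracked nutrients (densities per 100 g in the food table; daily intakes
#: in the same unit per day). Energy is carried alongside as "energy_kcal".
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "total_protein_g",
    "plant_protein_g",
    "animal_protein_g",
    "total_lipid_g",
    "safa_g",
    "fiber_g",
    "vitA_ug",
    "vitB12_ug",
    "vitB6_mg",
    "vitB2_mg",
    "calcium_mg",
    "sodium_mg",
)

#: Micronutrients with an Estimated Average Requirement (EAR): vitamin A
#: (retinol activity equivalents), B12, B6, B2 and calcium.
EAR_NUTRIENTS: tuple[str, ...] = (
    "vitA_ug",
    "vitB12_ug",
    "vitB6_mg",
    "vitB2_mg",
    "calcium_mg",
)

FOOTPRINTS: tuple[str, ...] = (
    "ghg_kgco2eq_per_kg",
    "land_m2yr_per_kg",
    "water_l_per_kg",
)

SEXES: tuple[str, ...] = ("female", "male")

PROTEIN_SPLIT_TOL = 1e-9


class DataModelError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class Person:
    """A survey participant.

    weight_factor is the survey weight correcting the sample to the
    national sociodemographic composition; it must be positive.
    """

    person_id: str
    sex: str
    age: int
    weight_factor: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataModelError(f"unknown sex token {self.sex!r} for person {self.person_id}")
        if not 18 <= self.age <= 65:
            raise DataModelError(f"age {self.age} out of [18, 65] for person {self.person_id}")
        if not self.weight_factor > 0:
            raise DataModelError(f"non-positive weight_factor for person {self.person_id}")


@dataclass(frozen=True)
class ConsumptionRecord:
    """One food eaten by one person on one recall day, in grams."""

    person_id: str
    day_index: int
    food_id: str
    amount_g: float

    def __post_init__(self) -> None:
        if self.day_index not in (1, 2):
            raise DataModelError(f"day_index must be 1 or 2, got {self.day_index}")
        if not np.isfinite(self.amount_g) or self.amount_g < 0:
            raise DataModelError(
                f"amount_g must be finite and >= 0, got {self.amount_g} "
                f"(person {self.person_id}, food {self.food_id})"
            )


@dataclass(frozen=True)
class EARReference:
    """An Estimated Average Requirement for one nutrient and sex."""

    nutrient: str
    sex: str
    ear_value: float

    def __post_init__(self) -> None:
        if self.nutrient not in EAR_NUTRIENTS:
            raise DataModelError(f"nutrient {self.nutrient!r} has no EAR")
        if self.sex not in SEXES:
            raise DataModelError(f"unknown sex token {self.sex!r} in EAR table")
        if not self.ear_value > 0:
            raise DataModelError(f"ear_value must be > 0, got {self.ear_value}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataModelError(f"{what}: missing column(s) {missing}")


def read_persons(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read the survey-weight table -> DataFrame[person_id, sex, age, weight_factor]."""
    df = pd.read_csv(path, dtype={"person_id": str})
    _require_columns(df, ["person_id", "sex", "age", "weight_factor"], "persons table")
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            Person(row.person_id, row.sex, int(row.age), float(row.weight_factor))
        except DataModelError as exc:
            raise DataModelError(f"persons table row {i}: {exc}") from exc
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].tolist()
        raise DataModelError(f"duplicate person_id(s): {dup}")
    df["age"] = df["age"].astype(int)
    df["weight_factor"] = df["weight_factor"].astype(float)
    return df


def read_consumption(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read consumption records.

    Returns a DataFrame with columns [person_id, day_index, food_id,
    amount_g], one row per eating-occasion line, row order preserved.
    Duplicate (person, day, food) rows are allowed and kept separate:
    replacement in the scenario engine is per occurrence.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "food_id": str})
    _require_columns(df, ["person_id", "day_index", "food_id", "amount_g"], "consumption table")
    amounts = pd.to_numeric(df["amount_g"], errors="coerce")
    bad = ~np.isfinite(amounts) | (amounts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataModelError(
            f"consumption table row {row}: amount_g={df['amount_g'].iloc[row]!r} "
            "is not a finite non-negative number"
        )
    days = pd.to_numeric(df["day_index"], errors="coerce")
    if not days.isin([1, 2]).all():
        row = int(np.flatnonzero(~days.isin([1, 2]).to_numpy())[0])
        raise DataModelError(f"consumption table row {row}: day_index must be 1 or 2")
    out = df.copy()
    out["day_index"] = days.astype(int)
    out["amount_g"] = amounts.astype(float)
    return out


def read_food_table(
    path_composition: str | Path | io.IOBase,
    path_footprints: str | Path | io.IOBase,
    path_groups: str | Path | io.IOBase,
) -> pd.DataFrame:
    """Join composition, footprint and group membership into one food table.

    Emulates the join of a national food-composition database with a food
    life-cycle-assessment table. Returns a DataFrame indexed by food_id with
    the 13 nutrient densities per 100 g, the three footprint factors per kg,
    the consumed_group label and the is_red_meat flag.
    """
    comp = pd.read_csv(path_composition, dtype={"food_id": str})
    _require_columns(comp, ["food_id", "name", *NUTRIENTS], "composition table")
    foot = pd.read_csv(path_footprints, dtype={"food_id": str})
    _require_columns(foot, ["food_id", *FOOTPRINTS], "footprint table")
    grp = pd.read_csv(path_groups, dtype={"food_id": str})
    _require_columns(grp, ["food_id", "consumed_group", "is_red_meat"], "group table")

    ids = [set(comp["food_id"]), set(foot["food_id"]), set(grp["food_id"])]
    union = set.union(*ids)
    inter = set.intersection(*ids)
    if union != inter:
        raise DataModelError(
            f"food_id sets differ across the three files; offending ids: {sorted(union - inter)}"
        )

    table = (
        comp.set_index("food_id")
        .join(foot.set_index("food_id"))
        .join(grp.set_index("food_id"))
    )
    table["is_red_meat"] = table["is_red_meat"].astype(bool)
    for col in (*NUTRIENTS, *FOOTPRINTS):
        vals = pd.to_numeric(table[col], errors="raise").astype(float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            bad_ids = table.index[(vals < 0) | ~np.isfinite(vals)].tolist()
            raise DataModelError(f"negative or non-finite {col} for foods {bad_ids}")
        table[col] = vals
    split_err = (
        table["plant_protein_g"] + table["animal_protein_g"] - table["total_protein_g"]
    ).abs()
    if (split_err > PROTEIN_SPLIT_TOL).any():
        bad_ids = table.index[split_err > PROTEIN_SPLIT_TOL].tolist()
        raise DataModelError(
            f"plant + animal protein != total protein for foods {bad_ids}"
        )
    return table


def read_replacement_mapping(path: str | Path | io.IOBase) -> dict[str, list[str]]:
    """Read the consumed_group -> ordered replacement food_id list mapping."""
    df = pd.read_csv(path, dtype={"consumed_group": str, "food_id": str})
    _require_columns(df, ["consumed_group", "food_id"], "replacement mapping")
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.consumed_group, []).append(row.food_id)
    for group, foods in mapping.items():
        if len(foods) < 1:
            raise DataModelError(f"empty replacement list for group {group}")
    return mapping


def validate_mapping(
    mapping: Mapping[str, Sequence[str]],
    food_table: pd.DataFrame,
    mixed_ok: Iterable[str] = (),
) -> None:
    """Check mapping invariants against the food table.

    Every listed food must exist, and replacement foods must carry zero
    animal protein unless explicitly flagged as mixed (e.g. vegetarian
    cheese) via ``mixed_ok``.
    """
    mixed = set(mixed_ok)
    for group, foods in mapping.items():
        unknown = [f for f in foods if f not in food_table.index]
        if unknown:
            raise DataModelError(f"mapping for {group} lists unknown foods {unknown}")
        animal = food_table.loc[list(foods), "animal_protein_g"]
        offenders = [f for f, a in animal.items() if a > 0 and f not in mixed]
        if offenders:
            raise DataModelError(
                f"replacement foods with animal protein in group {group}: {offenders}"
            )


def validate_consumption(records: pd.DataFrame, food_table: pd.DataFrame) -> None:
    """Every consumption record's food_id must join to exactly one food."""
    unknown = sorted(set(records["food_id"]) - set(food_table.index))
    if unknown:
        raise DataModelError(f"consumption references unknown food_id(s): {unknown}")


def read_ear_table(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read the EAR reference table -> DataFrame[nutrient, sex, ear_value]."""
    df = pd.read_csv(path)
    _require_columns(df, ["nutrient", "sex", "ear_value"], "EAR table")
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            EARReference(row.nutrient, row.sex, float(row.ear_value))
        except DataModelError as exc:
            raise DataModelError(f"EAR table row {i}: {exc}") from exc
    df["ear_value"] = df["ear_value"].astype(float)
    return df


def ear_lookup(ear_table: pd.DataFrame, nutrient: str, sex: str) -> float:
    sel = ear_table[(ear_table["nutrient"] == nutrient) & (ear_table["sex"] == sex)]
    if len(sel) != 1:
        raise DataModelError(f"EAR table has {len(sel)} rows for ({nutrient}, {sex})")
    return float(sel["ear_value"].iloc[0])


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("sex", "scenario", "strategy", "metric", "value", "ci_lo", "ci_hi")


@dataclass
class ScenarioReport:
    """Tidy result container: one row per (sex, scenario, strategy, metric).

    ``sex`` may also be "total" for population-level footprint rows, and
    ``ci_lo``/``ci_hi`` are NaN for deterministic metrics.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(REPORT_COLUMNS))
    )

    def add(self, sex: str, scenario: str, strategy: str, metric: str,
            value: float, ci_lo: float = np.nan, ci_hi: float = np.nan) -> None:
        self.rows.loc[len(self.rows)] = [sex, scenario, strategy, metric, value, ci_lo, ci_hi]

    def frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        for c in ("value", "ci_lo", "ci_hi"):
            out[c] = pd.to_numeric(out[c])
        return out


def write_report(report: ScenarioReport, path: str | Path) -> None:
    """Write the tidy report CSV (12 significant digits, stable column order)."""
    report.frame().to_csv(path, index=False, float_format="%.12g", columns=list(REPORT_COLUMNS))


def read_report(path: str | Path) -> ScenarioReport:
    df = pd.read_csv(path, dtype={c: str for c in ("sex", "scenario", "strategy", "metric")})
    _require_columns(df, REPORT_COLUMNS, "report")
    return ScenarioReport(rows=df[list(REPORT_COLUMNS)].copy())
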