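"""Survey-weighted per-capita daily environmental footprints of a diet.

Three indicators per food, all per kg: greenhouse-gas emission
(kg CO2-eq), land use (m^2 * year) and freshwater consumption (liters).
Diet footprints are linear in amounts: per person-day, indicator =
sum over records of amount_g / 1000 x factor_per_kg. Population values
average each person across recall days first and then weight across
persons with the survey weights; relative differences are expressed in
percent versus the reference diet. LCA factors are treated as point
values (no uncertainty propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd

from .data_model import FOOTPRINTS, DataModelError

SLICES = ("total", "female", "male")


@dataclass
class FootprintSummary:
    """Per-capita daily footprints for one scenario and population slice."""

    scenario: str
    population_slice: str
    ghg_kgco2eq_per_day: float
    land_m2yr_per_day: float
    water_l_per_day: float
    relative_diff_vs_reference: dict[str, float] = field(default_factory=dict)
    group_contributions: pd.DataFrame | None = None

    def as_series(self) -> pd.Series:
        return pd.Series({
            "ghg_kgco2eq_per_day": self.ghg_kgco2eq_per_day,
            "land_m2yr_per_day": self.land_m2yr_per_day,
            "water_l_per_day": self.water_l_per_day,
        })


def person_day_footprint(records: pd.DataFrame, food_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(person, day) indicator vector: sum of amount_g/1000 x factor/kg."""
    unknown = set(records["food_id"]) - set(food_table.index)
    if unknown:
        raise DataModelError(f"records reference unknown food_id(s): {sorted(unknown)}")
    factors = food_table.loc[records["food_id"], list(FOOTPRINTS)].to_numpy()
    contrib = pd.DataFrame(factors * records["amount_g"].to_numpy()[:, None] / 1000.0,
                           columns=list(FOOTPRINTS))
    contrib["person_id"] = records["person_id"].to_numpy()
    contrib["day_index"] = records["day_index"].to_numpy()
    return contrib.groupby(["person_id", "day_index"]).sum()


def population_footprint(
    person_day_footprints: pd.DataFrame,
    persons: pd.DataFrame,
    population_slice: str = "total",
    scenario: str = "",
    reference: FootprintSummary | None = None,
) -> FootprintSummary:
    """Survey-weighted mean daily footprint over a population slice.

    Each person's days are averaged first, then persons are weighted by
    weight_factor. With a reference summary given, relative differences
    are 100 x (scenario - reference) / reference per indicator.
    """
    if population_slice not in SLICES:
        raise DataModelError(f"unknown population slice {population_slice!r}")
    sel = persons if population_slice == "total" else persons[
        persons["sex"] == population_slice]
    if sel.empty:
        raise DataModelError(f"empty population slice {population_slice!r}")
    person_means = person_day_footprints.groupby(level="person_id").mean()
    merged = person_means.join(sel.set_index("person_id")["weight_factor"], how="inner")
    if merged.empty:
        raise DataModelError(f"no footprint rows for slice {population_slice!r}")
    w = merged.pop("weight_factor").to_numpy()
    means = merged.mul(w, axis=0).sum() / w.sum()
    summary = FootprintSummary(
        scenario=scenario, population_slice=population_slice,
        ghg_kgco2eq_per_day=float(means["ghg_kgco2eq_per_kg"]),
        land_m2yr_per_day=float(means["land_m2yr_per_kg"]),
        water_l_per_day=float(means["water_l_per_kg"]),
    )
    if reference is not None:
        ref = reference.as_series()
        cur = summary.as_series()
        summary.relative_diff_vs_reference = {
            k.replace("_per_day", ""): float(100.0 * (cur[k] - ref[k]) / ref[k])
            for k in cur.index
        }
    return summary


def group_contributions(
    records: pd.DataFrame,
    food_table: pd.DataFrame,
    persons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Share of each consumed_group in each indicator's population total.

    Foods without a recognized group fall in the "other" bucket. With
    persons given, record contributions are survey-weighted. Shares per
    indicator sum to 1; an indicator with zero total gets NaN shares.
    """
    unknown = set(records["food_id"]) - set(food_table.index)
    if unknown:
        raise DataModelError(f"records reference unknown food_id(s): {sorted(unknown)}")
    factors = food_table.loc[records["food_id"], list(FOOTPRINTS)].to_numpy()
    amounts = records["amount_g"].to_numpy()[:, None] / 1000.0
    contrib = pd.DataFrame(factors * amounts, columns=list(FOOTPRINTS))
    if persons is not None:
        wmap = persons.set_index("person_id")["weight_factor"]
        contrib = contrib.mul(records["person_id"].map(wmap).to_numpy(), axis=0)
    groups = food_table.loc[records["food_id"], "consumed_group"].fillna("other").to_numpy()
    contrib["consumed_group"] = groups
    totals = contrib.groupby("consumed_group").sum()
    grand = totals.sum(axis=0)
    shares = totals / grand.where(grand != 0)
    return shares
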