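"""Replacement scenarios: substitute meat/dairy consumption with plant-based
alternatives under the equal-weight (quantity) or equal-energy strategy.

The four replacement scenarios mirror the study design:

* ``no_meat_and_dairy`` — all meat and dairy records replaced;
* ``no_meat``           — all meat records replaced, dairy untouched;
* ``half_meat``         — 50% of every targeted meat record's grams replaced
                          (per-record split, deterministic in the fraction);
* ``no_red_meat``       — only records of red-meat foods replaced.

For each targeted consumption record one replacement food is drawn
uniformly (with replacement) from the consumed group's candidate list,
using a stream seeded by the scenario's allocation seed; the probability of
every candidate is equal. Under the quantity strategy the replacement
carries exactly the replaced grams; under the energy strategy the grams are
adjusted so the replacement provides the same kilocalories as the replaced
grams did.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import NUTRIENTS, DataModelError

SCENARIO_NAMES = ("reference", "no_meat_and_dairy", "no_meat", "half_meat", "no_red_meat")
STRATEGIES = ("quantity", "energy")

#: Energy-strategy guard: candidates with energy density below this (kcal/g)
#: are excluded from the candidate list to prevent unbounded gram inflation.
ED_MIN_KCAL_PER_G = 0.05


class ScenarioError(ValueError):
    """Raised for invalid scenario specifications or unreplaceable groups."""


def _groups_for(name: str, vocabulary: Sequence[str]) -> frozenset[str]:
    meat = frozenset(g for g in vocabulary if str(g).startswith("meat"))
    dairy = frozenset(g for g in vocabulary if str(g).startswith("dairy"))
    if name == "reference":
        return frozenset()
    if name == "no_meat_and_dairy":
        return meat | dairy
    if name in ("no_meat", "half_meat", "no_red_meat"):
        return meat
    raise ScenarioError(f"unknown scenario name {name!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario x strategy combination.

    target_groups defaults from the scenario name and the food table's
    group vocabulary (groups named meat_*/dairy_*); red_meat_only
    restricts the targeted records to foods flagged as red meat.
    """

    name: str
    strategy: str = "quantity"
    fraction_replaced: float = 1.0
    allocation_seed: int = 0
    target_groups: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ScenarioError(f"unknown scenario name {self.name!r}")
        if self.strategy not in STRATEGIES:
            raise ScenarioError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.fraction_replaced <= 1.0:
            raise ScenarioError("fraction_replaced must lie in (0, 1]")

    @property
    def red_meat_only(self) -> bool:
        return self.name == "no_red_meat"


def make_scenario(name: str, strategy: str = "quantity", master_seed: int = 0) -> ScenarioSpec:
    """Build the standard scenario with its conventional fraction and a
    per-(scenario, strategy) child seed derived by stable hashing, so every
    scenario has a fixed, reproducible allocation."""
    frac = 0.5 if name == "half_meat" else 1.0
    tag = f"{name}:{strategy}".encode()
    child = (master_seed * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1)
    return ScenarioSpec(name=name, strategy=strategy, fraction_replaced=frac,
                        allocation_seed=child)


def default_scenarios(master_seed: int = 0,
                      strategies: Sequence[str] = STRATEGIES) -> list[ScenarioSpec]:
    """Reference plus the four replacement scenarios under each strategy."""
    out = [make_scenario("reference", "quantity", master_seed)]
    for name in SCENARIO_NAMES[1:]:
        for strat in strategies:
            out.append(make_scenario(name, strat, master_seed))
    return out


# ---------------------------------------------------------------------------
# Scenario application
# ---------------------------------------------------------------------------


def apply_scenario(
    records: pd.DataFrame,
    food_table: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
    spec: ScenarioSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply one replacement scenario to a consumption dataset.

    Returns (new_records, events). Non-targeted records are bit-identical
    to the input; each targeted record loses fraction_replaced of its grams
    (dropped entirely at fraction 1) and is followed by a replacement
    record for one uniformly drawn candidate. The output preserves the
    stable input order, replacement rows directly after their originals.
    events has one row per replacement with the original index, grams
    removed, replacement food and grams added.
    """
    unknown = set(records["food_id"]) - set(food_table.index)
    if unknown:
        raise DataModelError(f"records reference unknown food_id(s): {sorted(unknown)}")

    target_groups = (spec.target_groups if spec.target_groups is not None
                     else _groups_for(spec.name, food_table["consumed_group"].unique()))
    if spec.name == "reference" or not target_groups:
        return records.copy(), _empty_events()

    group_of = records["food_id"].map(food_table["consumed_group"])
    targeted = group_of.isin(target_groups).to_numpy()
    if spec.red_meat_only:
        targeted &= records["food_id"].map(food_table["is_red_meat"]).to_numpy()

    missing = sorted(set(group_of[targeted]) - set(mapping))
    if missing:
        raise ScenarioError(f"targeted group(s) without replacement mapping: {missing}")

    energy_per_g = food_table["energy_kcal"] / 100.0
    candidates: dict[str, np.ndarray] = {}
    for g in set(group_of[targeted]):
        cand = np.asarray(mapping[g], dtype=object)
        if spec.strategy == "energy":
            ed = energy_per_g.loc[list(cand)].to_numpy()
            cand = cand[ed > ED_MIN_KCAL_PER_G]
            if len(cand) == 0:
                raise ScenarioError(
                    f"energy strategy: all candidates for group {g!r} have energy "
                    f"density <= {ED_MIN_KCAL_PER_G} kcal/g")
        candidates[g] = cand

    rng = np.random.default_rng(spec.allocation_seed)
    t_idx = np.flatnonzero(targeted)
    # one uniform draw per targeted record, in stable record order
    draws = np.empty(len(t_idx), dtype=object)
    for j, i in enumerate(t_idx):
        cand = candidates[group_of.iat[i]]
        draws[j] = cand[rng.integers(0, len(cand))]

    replaced_g = records["amount_g"].to_numpy()[t_idx] * spec.fraction_replaced
    if spec.strategy == "quantity":
        replacement_g = replaced_g.copy()
    else:
        ed_orig = energy_per_g.loc[records["food_id"].to_numpy()[t_idx]].to_numpy()
        ed_repl = energy_per_g.loc[list(draws)].to_numpy()
        replacement_g = replaced_g * ed_orig / ed_repl

    events = pd.DataFrame({
        "record_index": t_idx,
        "person_id": records["person_id"].to_numpy()[t_idx],
        "day_index": records["day_index"].to_numpy()[t_idx],
        "original_food_id": records["food_id"].to_numpy()[t_idx],
        "replaced_g": replaced_g,
        "replacement_food_id": draws,
        "replacement_g": replacement_g,
    })

    out = records.copy().reset_index(drop=True)
    out["_pos"] = np.arange(len(out), dtype=float)
    out.loc[t_idx, "amount_g"] = out.loc[t_idx, "amount_g"] * (1.0 - spec.fraction_replaced)
    repl_rows = pd.DataFrame({
        "person_id": events["person_id"],
        "day_index": events["day_index"],
        "food_id": events["replacement_food_id"].astype(str),
        "amount_g": events["replacement_g"],
        "_pos": t_idx + 0.5,
    })
    out = pd.concat([out, repl_rows], ignore_index=True)
    if spec.fraction_replaced >= 1.0:
        out = out[out["amount_g"] > 0.0]
    out = out.sort_values("_pos", kind="stable").drop(columns="_pos").reset_index(drop=True)
    out["day_index"] = out["day_index"].astype(int)
    return out, events


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "record_index", "person_id", "day_index", "original_food_id",
        "replaced_g", "replacement_food_id", "replacement_g"])


# ---------------------------------------------------------------------------
# Nutrient totals and allocation variability
# ---------------------------------------------------------------------------


def nutrient_totals(
    records: pd.DataFrame,
    food_table: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    n_days: int = 2,
) -> pd.DataFrame:
    """Per-(person, day) nutrient intake: sum of amount_g x density/100.

    With ``persons`` given, the result is reindexed on the full
    person x day grid, empty days filled with zero vectors.
    """
    unknown = set(records["food_id"]) - set(food_table.index)
    if unknown:
        raise DataModelError(f"records reference unknown food_id(s): {sorted(unknown)}")
    dens = food_table.loc[records["food_id"], list(NUTRIENTS)].to_numpy()
    contrib = pd.DataFrame(dens * records["amount_g"].to_numpy()[:, None] / 100.0,
                           columns=list(NUTRIENTS))
    contrib["person_id"] = records["person_id"].to_numpy()
    contrib["day_index"] = records["day_index"].to_numpy()
    totals = contrib.groupby(["person_id", "day_index"]).sum()
    if persons is not None:
        grid = pd.MultiIndex.from_product(
            [persons["person_id"], range(1, n_days + 1)], names=["person_id", "day_index"])
        totals = totals.reindex(grid, fill_value=0.0)
    return totals


def weighted_mean_intake(
    totals: pd.DataFrame, persons: pd.DataFrame
) -> pd.Series:
    """Survey-weighted population mean daily intake per nutrient
    (person-day totals averaged within person, then weighted across persons)."""
    person_means = totals.groupby(level="person_id").mean()
    merged = person_means.join(persons.set_index("person_id")["weight_factor"], how="inner")
    w = merged.pop("weight_factor").to_numpy()
    return merged.mul(w, axis=0).sum() / w.sum()


def replicate_allocation_cv(
    records: pd.DataFrame,
    food_table: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
    spec: ScenarioSpec,
    n_replicates: int = 10,
    outcome_fn: Callable[[pd.DataFrame], pd.Series] | None = None,
    persons: pd.DataFrame | None = None,
) -> pd.Series:
    """Coefficient of variation of outcomes across random-allocation replicates.

    Re-runs apply_scenario with allocation seeds seed+1 .. seed+n and
    returns sd/mean per outcome (ddof=1). outcome_fn defaults to the
    survey-weighted population mean intake per nutrient (requires persons).
    Outcomes with zero mean are reported as NaN (CV undefined).
    """
    if n_replicates < 2:
        raise ScenarioError("n_replicates must be >= 2")
    if outcome_fn is None:
        if persons is None:
            raise ScenarioError("default outcome_fn requires persons")
        outcome_fn = lambda recs: weighted_mean_intake(  # noqa: E731
            nutrient_totals(recs, food_table, persons), persons)
    outcomes = []
    for r in range(1, n_replicates + 1):
        rep_spec = ScenarioSpec(
            name=spec.name, strategy=spec.strategy,
            fraction_replaced=spec.fraction_replaced,
            allocation_seed=spec.allocation_seed + r,
            target_groups=spec.target_groups)
        new_records, _ = apply_scenario(records, food_table, mapping, rep_spec)
        outcomes.append(outcome_fn(new_records))
    frame = pd.DataFrame(outcomes)
    mean = frame.mean()
    cv = frame.std(ddof=1) / mean.where(mean != 0)
    return cv
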