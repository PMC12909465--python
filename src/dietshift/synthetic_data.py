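"""Synthetic two-recall survey, food database, footprints and EARs.

The generator emulates the statistical structure the downstream analysis
assumes, with known ground truth, so every stage is testable without the
restricted national survey / food-composition / LCA datasets:

* a two-recall survey of 600 women and 585 men aged 18-65 with positive
  survey weights (mean 1 per sex);
* a food database with meat and dairy consumed subgroups, plant-based
  replacement groups averaging 12 alternatives (range 1-31), a plant/animal
  protein split per food, and per-kg footprint factors in which plant foods
  have lower greenhouse-gas and land factors but higher water factors than
  the animal foods they replace;
* daily nutrient intakes that follow a one-part habitual-intake model
  exactly: Box-Cox transformed daily intake = sex-level mean
  + age_slope*(age-40) + b_i + e_ij, with b_i ~ N(0, sigma_b^2) between
  persons and e_ij ~ N(0, sigma_w^2) within persons.

The last point is achieved by drawing a realistic eating-occasion menu for
each person-day and then minimally adjusting the record amounts (a
regularized non-negative least-squares step, polished to an exact
equality-constrained solution) so that all independent nutrient totals hit
the latent model targets exactly. One standard-normal person factor and one
day factor are shared across nutrients, so any fixed linear combination of
nutrient totals (e.g. total = plant + animal protein) also follows the
model exactly when nutrients share lambda and the variance components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import EAR_NUTRIENTS, FOOTPRINTS, NUTRIENTS, SEXES

# Nutrients entering the exact-realization constraint system. Total protein
# is excluded: it is implied by the plant + animal split of every food.
CONSTRAINT_NUTRIENTS: tuple[str, ...] = tuple(
    n for n in NUTRIENTS if n != "total_protein_g"
)

# Sub-seed tags so each generator stage has an independent stream.
_SEED_POPULATION = 11
_SEED_FOOD_DB = 22
_SEED_CONSUMPTION = 33


@dataclass(frozen=True)
class GroupTemplate:
    """Eating-occasion structure of one consumed food group.

    rate is the Poisson mean of occasions/day; min_occasions floors the
    draw (staple groups have min >= 1 so every nutrient is consumed daily);
    amount_g is the mean grams per occasion for women (men are scaled by
    male_amount_factor); density_class selects the nutrient/footprint
    profile.
    """

    name: str
    kind: str  # "meat" | "dairy" | "staple"
    rate: float
    min_occasions: int
    amount_g: float
    density_class: str


# Mean densities per 100 g for each food class, in NUTRIENTS order minus
# total protein (protein given as (grams, plant_fraction)); footprints per kg.
# Plant classes: more fiber, zero B12 (unless fortified), lower SAFA; lower
# GHG/land but higher water than the animal classes they replace.
_CLASS_PROFILES: dict[str, dict[str, float]] = {
    "meat": dict(energy_kcal=200, protein=19, plant_frac=0.0, total_lipid_g=13,
                 safa_g=5.0, fiber_g=0.4, vitA_ug=15, vitB12_ug=1.5, vitB6_mg=0.35,
                 vitB2_mg=0.20, calcium_mg=15, sodium_mg=650,
                 ghg=7.0, land=6.0, water=45.0),          # red-meat foods override below
    "dairy": dict(energy_kcal=75, protein=5.0, plant_frac=0.0, total_lipid_g=4.0,
                  safa_g=2.5, fiber_g=0.0, vitA_ug=35, vitB12_ug=0.5, vitB6_mg=0.04,
                  vitB2_mg=0.18, calcium_mg=120, sodium_mg=80,
                  ghg=2.5, land=1.5, water=30.0),
    "repl_meat": dict(energy_kcal=180, protein=15, plant_frac=1.0, total_lipid_g=9.0,
                      safa_g=1.5, fiber_g=5.0, vitA_ug=5, vitB12_ug=0.0, vitB6_mg=0.15,
                      vitB2_mg=0.12, calcium_mg=80, sodium_mg=450,
                      ghg=2.5, land=2.5, water=180.0),
    "repl_dairy": dict(energy_kcal=60, protein=3.5, plant_frac=1.0, total_lipid_g=2.5,
                       safa_g=0.4, fiber_g=0.8, vitA_ug=3, vitB12_ug=0.0, vitB6_mg=0.04,
                       vitB2_mg=0.06, calcium_mg=100, sodium_mg=50,
                       ghg=0.9, land=0.9, water=90.0),
    "bread": dict(energy_kcal=250, protein=12, plant_frac=1.0, total_lipid_g=3.0,
                  safa_g=0.6, fiber_g=6.0, vitA_ug=1, vitB12_ug=0.0, vitB6_mg=0.10,
                  vitB2_mg=0.08, calcium_mg=40, sodium_mg=450,
                  ghg=1.2, land=1.5, water=120.0),
    "veg": dict(energy_kcal=30, protein=2.5, plant_frac=1.0, total_lipid_g=0.3,
                safa_g=0.05, fiber_g=2.5, vitA_ug=150, vitB12_ug=0.0, vitB6_mg=0.15,
                vitB2_mg=0.06, calcium_mg=40, sodium_mg=20,
                ghg=0.8, land=0.4, water=40.0),
    "fruit": dict(energy_kcal=55, protein=0.7, plant_frac=1.0, total_lipid_g=0.2,
                  safa_g=0.03, fiber_g=2.0, vitA_ug=25, vitB12_ug=0.0, vitB6_mg=0.08,
                  vitB2_mg=0.03, calcium_mg=10, sodium_mg=2,
                  ghg=0.7, land=0.5, water=80.0),
    "fish": dict(energy_kcal=160, protein=13, plant_frac=0.0, total_lipid_g=11,
                 safa_g=2.8, fiber_g=0.0, vitA_ug=80, vitB12_ug=3.0, vitB6_mg=0.30,
                 vitB2_mg=0.25, calcium_mg=40, sodium_mg=300,
                 ghg=4.5, land=2.0, water=35.0),
    "snacks": dict(energy_kcal=350, protein=13, plant_frac=1.0, total_lipid_g=15,
                   safa_g=4.0, fiber_g=3.0, vitA_ug=5, vitB12_ug=0.0, vitB6_mg=0.10,
                   vitB2_mg=0.06, calcium_mg=40, sodium_mg=400,
                   ghg=2.0, land=1.8, water=100.0),
    "fats": dict(energy_kcal=400, protein=0.5, plant_frac=1.0, total_lipid_g=42,
                 safa_g=9.0, fiber_g=0.0, vitA_ug=40, vitB12_ug=0.0, vitB6_mg=0.02,
                 vitB2_mg=0.02, calcium_mg=5, sodium_mg=700,
                 ghg=2.5, land=2.2, water=90.0),
}

# Red-meat foods get markedly heavier GHG/land factors than white/processed.
_RED_MEAT_FOOTPRINT = dict(ghg=18.0, land=14.0, water=65.0)

_MEAT_TEMPLATES = [
    (0.70, 1, 55.0), (0.60, 1, 30.0), (0.35, 0, 25.0), (0.35, 0, 25.0), (0.35, 0, 25.0),
]
_DAIRY_TEMPLATES = [
    (0.80, 1, 110.0), (0.60, 1, 100.0), (0.90, 1, 25.0), (0.50, 1, 80.0),
    (0.30, 0, 25.0), (0.30, 0, 25.0), (0.30, 0, 25.0), (0.30, 0, 25.0), (0.30, 0, 25.0),
]
_STAPLE_TEMPLATES = [
    ("bread_cereals", 2.0, 2, 65.0, "bread"),
    ("vegetables", 1.3, 2, 90.0, "veg"),
    ("fruit", 1.1, 1, 110.0, "fruit"),
    ("fish_eggs", 0.6, 1, 55.0, "fish"),
    ("snacks_other", 1.4, 1, 45.0, "snacks"),
    ("fats_sauces", 1.5, 1, 15.0, "fats"),
]


def _default_groups(n_meat: int, n_dairy: int) -> tuple[GroupTemplate, ...]:
    groups: list[GroupTemplate] = []
    for i in range(n_meat):
        rate, mn, amt = _MEAT_TEMPLATES[i % len(_MEAT_TEMPLATES)]
        groups.append(GroupTemplate(f"meat_{i + 1}", "meat", rate, mn, amt, "meat"))
    for i in range(n_dairy):
        rate, mn, amt = _DAIRY_TEMPLATES[i % len(_DAIRY_TEMPLATES)]
        groups.append(GroupTemplate(f"dairy_{i + 1}", "dairy", rate, mn, amt, "dairy"))
    for name, rate, mn, amt, cls in _STAPLE_TEMPLATES:
        groups.append(GroupTemplate(name, "staple", rate, mn, amt, cls))
    return tuple(groups)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic survey.

    Defaults reproduce the reference conditions the analysis targets:
    585 men + 600 women, two recall days, 5 meat + 9 dairy consumed
    subgroups whose replacement lists average 12 alternatives (support
    1-31), within-group nutrient-density relative SD 0.2 (<= 0.3),
    red-meat probability 0.8 per meat food, and a lognormal (lambda = 0)
    intake model with sigma_b = 0.30 and sigma_w = 0.50 on the
    transformed scale for every nutrient.
    """

    n_women: int = 600
    n_men: int = 585
    n_groups_meat: int = 5
    n_groups_dairy: int = 9
    n_foods_per_group: int = 8
    alternatives_mean: float = 12.0
    alternatives_max: int = 31
    sigma_b: float | Mapping[str, float] = 0.30
    sigma_w: float | Mapping[str, float] = 0.50
    transform_lambda: float | Mapping[str, float] = 0.0
    age_slope: float | Mapping[str, float] = -0.003
    density_rel_sd: float = 0.20
    amount_rel_sd: float = 0.25
    male_amount_factor: float = 1.30
    red_meat_prob: float = 0.80
    fortify_b12: bool = False
    weight_rel_sd: float = 0.20
    master_seed: int = 2021

    def __post_init__(self) -> None:
        for name in ("sigma_b", "sigma_w"):
            if min(self._per_nutrient(name).values()) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.alternatives_mean <= self.alternatives_max <= 31:
            raise ValueError("alternatives distribution must have support within [1, 31]")
        if self.density_rel_sd < 0 or self.density_rel_sd > 0.3:
            raise ValueError("density_rel_sd must lie in [0, 0.3]")

    def _per_nutrient(self, name: str) -> dict[str, float]:
        val = getattr(self, name)
        if isinstance(val, Mapping):
            return {n: float(val.get(n, 0.0)) for n in NUTRIENTS}
        return {n: float(val) for n in NUTRIENTS}

    @property
    def groups(self) -> tuple[GroupTemplate, ...]:
        return _default_groups(self.n_groups_meat, self.n_groups_dairy)


@dataclass
class GroundTruth:
    """Generator-side latent values used as recovery oracles.

    habitual holds each person's latent habitual intake per nutrient
    (back-transformed linear predictor without the day effect); params
    holds per (nutrient, sex) the transformed-scale mean mu, sigma_b,
    sigma_w, lambda, age slope and the analytic population habitual mean.
    """

    person_effects: pd.DataFrame  # person_id, z
    habitual: pd.DataFrame        # person_id + one column per nutrient
    params: pd.DataFrame          # nutrient, sex, mu, sigma_b, sigma_w, lam, age_slope, true_mean
    n_fallback_days: int = 0      # person-days where the exact adjustment failed


@dataclass
class SyntheticDataset:
    persons: pd.DataFrame
    food_table: pd.DataFrame
    mapping: dict[str, list[str]]
    records: pd.DataFrame
    ground_truth: GroundTruth
    ear_table: pd.DataFrame | None = None
    n_fallback_days: int = 0


# ---------------------------------------------------------------------------
# Box-Cox helpers (shared with habitual_intake via import there)
# ---------------------------------------------------------------------------


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_inverse(t: np.ndarray, lam: float) -> np.ndarray:
    """Inverse Box-Cox; a negative base (lam > 0) is clamped at 0."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return np.exp(np.minimum(t, 700.0))
    base = lam * t + 1.0
    return np.power(np.maximum(base, 0.0), 1.0 / lam)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def generate_population(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate the survey sample: ages uniform on [18, 65] (integers),
    lognormal survey weights normalized to mean 1 within each sex."""
    rng = np.random.default_rng([spec.master_seed, _SEED_POPULATION])
    rows = []
    for sex, n, prefix in (("female", spec.n_women, "w"), ("male", spec.n_men, "m")):
        if n == 0:
            continue
        ages = rng.integers(18, 66, size=n)
        s = spec.weight_rel_sd
        weights = np.exp(rng.normal(-0.5 * s * s, s, size=n))
        weights = weights / weights.mean()
        for i in range(n):
            rows.append((f"{prefix}{i + 1:04d}", sex, int(ages[i]), float(weights[i])))
    return pd.DataFrame(rows, columns=["person_id", "sex", "age", "weight_factor"])


# ---------------------------------------------------------------------------
# Food database
# ---------------------------------------------------------------------------


def _draw_density(rng: np.random.Generator, mean: float, rel_sd: float) -> float:
    if mean == 0.0 or rel_sd == 0.0:
        return float(mean)
    sd_log = np.sqrt(np.log1p(rel_sd**2))
    return float(mean * np.exp(rng.normal(-0.5 * sd_log**2, sd_log)))


def _make_food_row(rng: np.random.Generator, food_id: str, name: str, group: str,
                   cls: str, rel_sd: float, is_red: bool, fortify_b12: bool) -> dict:
    prof = _CLASS_PROFILES[cls]
    protein = _draw_density(rng, prof["protein"], rel_sd)
    plant = protein * prof["plant_frac"]
    row = {"food_id": food_id, "name": name, "consumed_group": group,
           "is_red_meat": bool(is_red),
           "total_protein_g": protein, "plant_protein_g": plant,
           "animal_protein_g": protein - plant}
    for nut in CONSTRAINT_NUTRIENTS:
        if nut in ("plant_protein_g", "animal_protein_g"):
            continue
        mean = prof[nut]
        if nut == "vitB12_ug" and prof["plant_frac"] == 1.0 and fortify_b12:
            mean = 0.8  # fortified plant alternative
        row[nut] = _draw_density(rng, mean, rel_sd)
    fp = _RED_MEAT_FOOTPRINT if is_red else {k: prof[k] for k in ("ghg", "land", "water")}
    row["ghg_kgco2eq_per_kg"] = _draw_density(rng, fp["ghg"], rel_sd)
    row["land_m2yr_per_kg"] = _draw_density(rng, fp["land"], rel_sd)
    row["water_l_per_kg"] = _draw_density(rng, fp["water"], rel_sd)
    return row


def generate_food_database(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate the food table and the replacement mapping.

    Each meat/dairy consumed subgroup maps to a list of plant-based
    alternatives (animal protein exactly 0) whose length is
    1 + Binomial(alternatives_max - 1, p) with mean alternatives_mean,
    so the support is exactly [1, alternatives_max].
    """
    rng = np.random.default_rng([spec.master_seed, _SEED_FOOD_DB])
    rows: list[dict] = []
    mapping: dict[str, list[str]] = {}
    for g in spec.groups:
        for j in range(spec.n_foods_per_group):
            is_red = bool(g.kind == "meat" and rng.random() < spec.red_meat_prob)
            rows.append(_make_food_row(
                rng, f"{g.name}_f{j + 1}", f"{g.name} food {j + 1}", g.name,
                g.density_class, spec.density_rel_sd, is_red, False))
        if g.kind in ("meat", "dairy"):
            # 1 + Binomial(max-1, p): support exactly [1, alternatives_max],
            # mean alternatives_mean
            span = spec.alternatives_max - 1
            n_alt = int(1 + rng.binomial(span, (spec.alternatives_mean - 1.0) / span))
            cls = "repl_meat" if g.kind == "meat" else "repl_dairy"
            alt_ids = []
            for j in range(n_alt):
                fid = f"{g.name}_alt{j + 1}"
                rows.append(_make_food_row(
                    rng, fid, f"{g.name} alternative {j + 1}", "other",
                    cls, spec.density_rel_sd, False, spec.fortify_b12))
                alt_ids.append(fid)
            mapping[g.name] = alt_ids
    table = pd.DataFrame(rows).set_index("food_id")
    order = ["name", "consumed_group", "is_red_meat", *NUTRIENTS, *FOOTPRINTS]
    return table[order], mapping


# ---------------------------------------------------------------------------
# Latent intake model and expected base-menu totals
# ---------------------------------------------------------------------------


def _expected_occasions(rate: float, min_occ: int) -> float:
    """E[max(N, m)] for N ~ Poisson(rate)."""
    if min_occ == 0:
        return rate
    s = rate
    p = np.exp(-rate)
    for n in range(min_occ):
        s += (min_occ - n) * p
        p *= rate / (n + 1)
    return float(s)


def _expected_base_totals(
    spec: SyntheticSpec, sex: str, food_table: pd.DataFrame | None = None
) -> dict[str, float]:
    """Expected per-day nutrient totals of the un-adjusted menu, by sex.

    With a realized food table the group densities are the means over the
    group's generated foods (occasions choose foods uniformly); otherwise
    the class profile means are used.
    """
    factor = spec.male_amount_factor if sex == "male" else 1.0
    totals = {n: 0.0 for n in NUTRIENTS}
    for g in spec.groups:
        grams = _expected_occasions(g.rate, g.min_occasions) * g.amount_g * factor
        if food_table is not None:
            dens = food_table.loc[food_table["consumed_group"] == g.name, list(NUTRIENTS)]
            for nut in NUTRIENTS:
                totals[nut] += grams * float(dens[nut].mean()) / 100.0
        else:
            prof = _CLASS_PROFILES[g.density_class]
            totals["total_protein_g"] += grams * prof["protein"] / 100.0
            totals["plant_protein_g"] += grams * prof["protein"] * prof["plant_frac"] / 100.0
            totals["animal_protein_g"] += (
                grams * prof["protein"] * (1 - prof["plant_frac"]) / 100.0)
            for nut in CONSTRAINT_NUTRIENTS:
                if nut in ("plant_protein_g", "animal_protein_g"):
                    continue
                totals[nut] += grams * prof[nut] / 100.0
    return totals


def latent_params(spec: SyntheticSpec, food_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (nutrient, sex) latent model parameters and analytic habitual mean."""
    sb = spec._per_nutrient("sigma_b")
    sw = spec._per_nutrient("sigma_w")
    lams = spec._per_nutrient("transform_lambda")
    slopes = spec._per_nutrient("age_slope")
    # Gauss-Hermite nodes for E over the person effect; exact for lambda = 0.
    nodes, wts = np.polynomial.hermite.hermgauss(40)
    ages = np.arange(18, 66)
    rows = []
    for sex in SEXES:
        base = _expected_base_totals(spec, sex, food_table)
        for nut in NUTRIENTS:
            lam = lams[nut]
            mu = float(boxcox_transform(np.array([base[nut]]), lam)[0])
            grid = (mu + slopes[nut] * (ages[:, None] - 40.0)
                    + np.sqrt(2.0) * sb[nut] * nodes[None, :])
            true_mean = float((boxcox_inverse(grid, lam) * wts[None, :]).sum(axis=1).mean()
                              / np.sqrt(np.pi))
            rows.append((nut, sex, mu, sb[nut], sw[nut], lam, slopes[nut], true_mean))
    return pd.DataFrame(rows, columns=["nutrient", "sex", "mu", "sigma_b", "sigma_w",
                                       "lam", "age_slope", "true_mean"])


# ---------------------------------------------------------------------------
# Consumption records with exact model realization
# ---------------------------------------------------------------------------


def _adjust_amounts(a0: np.ndarray, dens: np.ndarray, target: np.ndarray,
                    reg: float = 1e-4) -> tuple[np.ndarray, bool]:
    """Minimally adjust provisional amounts so dens.T @ a == target, a >= 0.

    dens is (n_foods, n_constraints) in intake-units per gram. Solves a
    target-normalized NNLS regularized toward a0, then polishes toward the
    exact equality-constrained minimum-relative-change solution with an
    active-set loop (foods whose adjusted amount would go negative are
    pinned at zero one at a time). Returns (amounts, exact_flag).
    """
    n_f, n_c = dens.shape
    scale = np.where(target > 0, target, 1.0)
    d_sc = dens / scale[None, :]
    t_sc = target / scale
    A = np.vstack([d_sc.T, reg * np.diag(1.0 / a0)])
    b = np.concatenate([t_sc, reg * np.ones(n_f)])
    a, _ = nnls(A, b, maxiter=200 * n_f)
    support = a > 1e-12
    for _ in range(n_f):
        if support.sum() < n_c:
            break
        a0s = a0[support]
        ds = d_sc[support]
        c = a0s**2
        gram = ds.T @ (c[:, None] * ds)
        try:
            y = np.linalg.solve(gram, t_sc - ds.T @ a0s)
        except np.linalg.LinAlgError:
            break
        cand = a0s + c * (ds @ y)
        if cand.min() >= 0.0:
            a = np.zeros(n_f)
            a[support] = cand
            break
        rel = cand / a0s
        support[np.flatnonzero(support)[np.argmin(rel)]] = False
    resid = np.abs(d_sc.T @ a - t_sc)
    return a, bool(resid.max() < 1e-6)


def generate_consumption(
    population: pd.DataFrame,
    food_db: tuple[pd.DataFrame, dict[str, list[str]]] | pd.DataFrame,
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate two recall days per person plus the latent ground truth.

    For each person-day, eating occasions per group are Poisson draws
    floored at the group minimum (staples >= 1/day), each occasion picks a
    food uniformly within the group with a lognormal provisional amount,
    and the amounts are then adjusted so all nutrient totals equal the
    latent Box-Cox model targets exactly.
    """
    food_table = food_db[0] if isinstance(food_db, tuple) else food_db
    params = latent_params(spec, food_table)
    par = {(r.nutrient, r.sex): r for r in params.itertuples(index=False)}

    rng = np.random.default_rng([spec.master_seed, _SEED_CONSUMPTION])
    groups = spec.groups
    consumed = {
        g.name: food_table.index[(food_table["consumed_group"] == g.name)].to_numpy()
        for g in groups
    }
    dens_all = food_table[list(CONSTRAINT_NUTRIENTS)].to_numpy() / 100.0
    row_of = {fid: i for i, fid in enumerate(food_table.index)}

    n = len(population)
    z = rng.standard_normal(n)                    # shared person effect
    u = rng.standard_normal((n, 2))               # shared day effects
    sd_log_amt = np.sqrt(np.log1p(spec.amount_rel_sd**2))

    rec_person: list[str] = []
    rec_day: list[int] = []
    rec_food: list[str] = []
    rec_amount: list[float] = []
    n_fallback = 0

    sexes = population["sex"].to_numpy()
    ages = population["age"].to_numpy()
    pids = population["person_id"].to_numpy()
    amt_factor = np.where(sexes == "male", spec.male_amount_factor, 1.0)

    # Pre-draw occasion counts for all (person, day, group) at once.
    counts = {
        g.name: np.maximum(rng.poisson(g.rate, size=(n, 2)), g.min_occasions)
        for g in groups
    }
    exp_grams = {
        g.name: _expected_occasions(g.rate, g.min_occasions) * g.amount_g
        for g in groups
    }

    for i in range(n):
        sex = sexes[i]
        for d in (1, 2):
            food_rows: list[int] = []
            amounts: list[float] = []
            for g in groups:
                k = counts[g.name][i, d - 1]
                if k == 0:
                    continue
                choice = rng.integers(0, len(consumed[g.name]), size=k)
                amt = (g.amount_g * amt_factor[i]
                       * np.exp(rng.normal(-0.5 * sd_log_amt**2, sd_log_amt, size=k)))
                # pin the group's provisional grams at its expected total so the
                # menu profile stays close to the latent target direction; the
                # day-level variation is injected by the exact adjustment below
                amt *= exp_grams[g.name] * amt_factor[i] / amt.sum()
                for c, a in zip(choice, amt):
                    food_rows.append(row_of[consumed[g.name][c]])
                    amounts.append(float(a))
            idx = np.array(food_rows)
            a0 = np.array(amounts)
            dens = dens_all[idx]
            target = np.empty(len(CONSTRAINT_NUTRIENTS))
            for k_i, nut in enumerate(CONSTRAINT_NUTRIENTS):
                p = par[(nut, sex)]
                t_lin = (p.mu + p.age_slope * (ages[i] - 40.0)
                         + p.sigma_b * z[i] + p.sigma_w * u[i, d - 1])
                target[k_i] = boxcox_inverse(np.array([t_lin]), p.lam)[0]
            # pre-scale so total energy matches before the profile adjustment
            e_col = CONSTRAINT_NUTRIENTS.index("energy_kcal")
            base_energy = float(dens[:, e_col] @ a0)
            if base_energy > 0:
                a0 = a0 * (target[e_col] / base_energy)
            adj, exact = _adjust_amounts(a0, dens, target)
            for _retry in range(2):
                if exact:
                    break
                # target outside the menu's cone: widen it with one extra food
                # per group (a light second helping) and re-solve
                for g in groups:
                    c = rng.integers(0, len(consumed[g.name]))
                    idx = np.append(idx, row_of[consumed[g.name][c]])
                    a0 = np.append(a0, 0.3 * g.amount_g * amt_factor[i])
                dens = dens_all[idx]
                a0 = a0 * (target[e_col] / float(dens[:, e_col] @ a0))
                adj, exact = _adjust_amounts(a0, dens, target)
            if not exact:
                n_fallback += 1  # keep the near-feasible NNLS solution
            keep = adj > 1e-9
            for r, a in zip(idx[keep], adj[keep]):
                rec_person.append(pids[i])
                rec_day.append(d)
                rec_food.append(food_table.index[r])
                rec_amount.append(float(a))

    records = pd.DataFrame({
        "person_id": rec_person, "day_index": rec_day,
        "food_id": rec_food, "amount_g": rec_amount,
    })

    habit = {"person_id": pids}
    for nut in NUTRIENTS:
        vals = np.empty(n)
        for i in range(n):
            p = par[(nut, sexes[i])]
            t_lin = p.mu + p.age_slope * (ages[i] - 40.0) + p.sigma_b * z[i]
            vals[i] = boxcox_inverse(np.array([t_lin]), p.lam)[0]
        habit[nut] = vals
    gt = GroundTruth(
        person_effects=pd.DataFrame({"person_id": pids, "z": z}),
        habitual=pd.DataFrame(habit),
        params=params,
        n_fallback_days=n_fallback,
    )
    return records, gt


# ---------------------------------------------------------------------------
# EAR table
# ---------------------------------------------------------------------------


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, v))


def generate_ear_table(
    ground_truth: GroundTruth,
    persons: pd.DataFrame,
    quantile: float | Mapping[str, float] = 0.10,
) -> pd.DataFrame:
    """Plant each EAR at a quantile of the latent habitual distribution.

    The survey-weighted fraction of latent habitual intakes below the EAR
    then equals the requested quantile by construction, which gives the
    cut-point estimator a known truth. quantile may be per-nutrient.
    """
    merged = ground_truth.habitual.merge(
        persons[["person_id", "sex", "weight_factor"]], on="person_id")
    rows = []
    for nut in EAR_NUTRIENTS:
        q = quantile[nut] if isinstance(quantile, Mapping) else quantile
        if not 0.0 <= q < 1.0:
            raise ValueError("EAR quantile must lie in [0, 1)")
        for sex in SEXES:
            sub = merged[merged["sex"] == sex]
            if sub.empty:
                continue
            vals = sub[nut].to_numpy()
            wts = sub["weight_factor"].to_numpy()
            ear = vals.min() * 0.5 if q == 0.0 else _weighted_quantile(vals, wts, q)
            rows.append((nut, sex, float(ear)))
    return pd.DataFrame(rows, columns=["nutrient", "sex", "ear_value"])


# ---------------------------------------------------------------------------
# One-call generation and file output
# ---------------------------------------------------------------------------


def generate(spec: SyntheticSpec | None = None, ear_quantile: float = 0.10) -> SyntheticDataset:
    """Generate the full synthetic dataset under the spec's master seed."""
    spec = spec or SyntheticSpec()
    persons = generate_population(spec)
    food_table, mapping = generate_food_database(spec)
    records, gt = generate_consumption(persons, (food_table, mapping), spec)
    ear = generate_ear_table(gt, persons, ear_quantile)
    return SyntheticDataset(persons, food_table, mapping, records, gt, ear,
                            n_fallback_days=gt.n_fallback_days)


def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset as the CSV files the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.persons.to_csv(out / "persons.csv", index=False, float_format="%.12g")
    data.records.to_csv(out / "consumption.csv", index=False, float_format="%.12g")
    ft = data.food_table.reset_index()
    ft[["food_id", "name", *NUTRIENTS]].to_csv(
        out / "composition.csv", index=False, float_format="%.12g")
    ft[["food_id", *FOOTPRINTS]].to_csv(
        out / "footprints.csv", index=False, float_format="%.12g")
    ft[["food_id", "consumed_group", "is_red_meat"]].to_csv(out / "groups.csv", index=False)
    pd.DataFrame(
        [(g, f) for g, foods in data.mapping.items() for f in foods],
        columns=["consumed_group", "food_id"],
    ).to_csv(out / "mapping.csv", index=False)
    if data.ear_table is not None:
        data.ear_table.to_csv(out / "ear.csv", index=False, float_format="%.12g")
    data.ground_truth.habitual.to_csv(out / "ground_truth.csv", index=False,
                                      float_format="%.12g")
    data.ground_truth.params.to_csv(out / "ground_truth_params.csv", index=False,
                                    float_format="%.12g")
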