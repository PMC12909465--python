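"""End-to-end orchestration: simulate -> scenarios -> habitual intakes ->
EAR adequacy -> footprints -> tidy report.

Every random draw is traceable to the master seed: the synthetic survey
uses it directly, each scenario x strategy gets a child allocation seed by
stable hashing, and each bootstrap stream is derived from the master seed
and the scenario/sex labels. Plant-protein shares are ratios of
survey-weighted mean habitual intakes (ratio of means, matching the
population-level framing of the reported percentages).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    NUTRIENTS, SEXES, DataModelError, ScenarioReport, read_consumption,
    read_ear_table, read_food_table, read_persons, read_replacement_mapping,
    write_report,
)
from .environment import group_contributions, person_day_footprint, population_footprint
from .habitual_intake import (
    AdequacyEstimate, HabitualModel, bootstrap_ci, compare_scenarios,
    fit_habitual_model, habitual_distribution, proportion_below,
)
from .scenario_engine import (
    STRATEGIES, ScenarioSpec, apply_scenario, make_scenario, nutrient_totals,
    replicate_allocation_cv,
)
from .synthetic_data import SyntheticDataset, SyntheticSpec, generate, write_dataset

logger = logging.getLogger(__name__)

#: Plant-protein policy targets: current status quo ~40%, short-term
#: national target 50%, long-term target 60%.
PLANT_PROTEIN_TARGETS = {"current": 0.40, "short_term": 0.50, "long_term": 0.60}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    data_dir: str | None = None          # None -> simulate synthetic data
    out_dir: str | None = None
    scenario_names: Sequence[str] = ("no_meat_and_dairy", "no_meat", "half_meat", "no_red_meat")
    strategies: Sequence[str] = STRATEGIES
    master_seed: int = 2021
    n_boot: int = 200
    n_replicates_cv: int = 10
    compute_allocation_cv: bool = False
    nutrients: Sequence[str] = NUTRIENTS
    ear_concern_threshold: float = 0.10
    plant_protein_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(PLANT_PROTEIN_TARGETS))
    synthetic: SyntheticSpec | None = None
    ear_quantile: float = 0.10
    min_persons: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.ear_concern_threshold < 1:
            raise ValueError("ear_concern_threshold must lie in (0, 1)")
        for k, v in self.plant_protein_targets.items():
            if not 0 < v < 1:
                raise ValueError(f"plant-protein target {k} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticSpec(**syn)
        return cfg


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    models: dict[tuple[str, str], HabitualModel]            # (sex, nutrient)
    habitual_means: dict[tuple[str, str], float]
    habitual_cis: dict[tuple[str, str], tuple[float, float]]
    adequacy: list[AdequacyEstimate]
    plant_protein_share: dict[str, float]                   # per sex
    footprints: dict[str, "object"]                         # per slice
    contributions: pd.DataFrame


@dataclass
class PipelineResult:
    config: RunConfig
    report: ScenarioReport
    scenarios: dict[tuple[str, str], ScenarioResult]
    allocation_cv: dict[tuple[str, str], pd.Series]
    log_events: list[dict]

    def scenario(self, name: str, strategy: str = "quantity") -> ScenarioResult:
        return self.scenarios[(name, strategy)]


def _load_dataset(config: RunConfig) -> SyntheticDataset:
    if config.data_dir is None:
        spec = config.synthetic or SyntheticSpec(master_seed=config.master_seed)
        return generate(spec, ear_quantile=config.ear_quantile)
    d = Path(config.data_dir)
    persons = read_persons(d / "persons.csv")
    records = read_consumption(d / "consumption.csv")
    food = read_food_table(d / "composition.csv", d / "footprints.csv", d / "groups.csv")
    mapping = read_replacement_mapping(d / "mapping.csv")
    ear = read_ear_table(d / "ear.csv") if (d / "ear.csv").exists() else None
    return SyntheticDataset(persons, food, mapping, records, None, ear)


def plant_protein_share(
    distributions: Mapping[str, "object"] | Mapping[str, float]
) -> float:
    """Plant-based share of total protein from habitual distributions.

    Accepts a mapping with keys "plant_protein_g" and "total_protein_g"
    whose values are HabitualDistribution objects (their summary means are
    used) or plain weighted means. Ratio of means, not mean of ratios.
    """
    def _mean(v):
        return v.summary["mean"] if hasattr(v, "summary") else float(v)

    plant = _mean(distributions["plant_protein_g"])
    total = _mean(distributions["total_protein_g"])
    if total <= 0:
        raise DataModelError("total protein mean is zero; share undefined")
    return plant / total


def classify_against_targets(
    share: float, targets: Mapping[str, float] | None = None
) -> dict[str, bool | str]:
    """Label a plant-protein share against the 50%/60% transition targets."""
    t = dict(targets or PLANT_PROTEIN_TARGETS)
    if not 0 <= share <= 1:
        raise ValueError("share must lie in [0, 1]")
    meets_short = share >= t["short_term"]
    meets_long = share >= t["long_term"]
    label = ("meets_long_term" if meets_long
             else "meets_short_term" if meets_short else "below_short_term")
    return {"meets_short_term": meets_short, "meets_long_term": meets_long,
            "label": label}


def _boot_seed(master_seed: int, scenario: str, strategy: str, sex: str) -> int:
    tag = f"boot:{scenario}:{strategy}:{sex}".encode()
    return (master_seed * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1)


def _scenario_stats(
    totals: pd.DataFrame,
    persons: pd.DataFrame,
    sex: str,
    nutrients: Sequence[str],
    ear_values: Mapping[str, float],
    lam_fixed: Mapping[str, float] | None,
    min_persons: int,
) -> dict[str, float]:
    """Habitual means (and EAR proportions) for one sex on one dataset."""
    out: dict[str, float] = {}
    dists = {}
    for nut in nutrients:
        grid = (lam_fixed[nut],) if lam_fixed else None
        kwargs = {"lambda_grid": grid} if grid else {}
        model = fit_habitual_model(totals, persons, nut, sex,
                                   min_persons=min_persons, **kwargs)
        dist = habitual_distribution(model, persons, totals)
        dists[nut] = dist
        out[f"habitual_mean_{nut}"] = dist.summary["mean"]
        if nut in ear_values:
            out[f"prop_below_ear_{nut}"] = proportion_below(dist, ear_values[nut])
    if "plant_protein_g" in dists and "total_protein_g" in dists:
        out["plant_protein_share"] = plant_protein_share(dists)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order and assemble the tidy report.

    Stages: load or simulate the survey; apply each scenario x strategy;
    estimate habitual intake distributions per sex and nutrient; compute
    EAR adequacy with bootstrap CIs; compute footprints with relative
    differences versus reference; flag CI non-overlap versus reference.
    """
    log_events: list[dict] = []
    data = _load_dataset(config)
    if data.n_fallback_days:
        log_events.append({"event": "generator_fallback_days",
                           "count": data.n_fallback_days})

    specs = [make_scenario("reference", "quantity", config.master_seed)]
    for name in config.scenario_names:
        for strat in config.strategies:
            specs.append(make_scenario(name, strat, config.master_seed))

    ear_by_sex: dict[str, dict[str, float]] = {s: {} for s in SEXES}
    if data.ear_table is not None:
        for row in data.ear_table.itertuples(index=False):
            ear_by_sex[row.sex][row.nutrient] = float(row.ear_value)

    report = ScenarioReport()
    results: dict[tuple[str, str], ScenarioResult] = {}
    allocation_cv: dict[tuple[str, str], pd.Series] = {}
    reference_fp: dict[str, object] = {}
    sexes_present = [s for s in SEXES if (data.persons["sex"] == s).any()]

    for spec in specs:
        try:
            new_records, events = apply_scenario(
                data.records, data.food_table, data.mapping, spec)
        except Exception as exc:
            raise RuntimeError(
                f"stage scenario ({spec.name}/{spec.strategy}) failed: {exc}") from exc
        log_events.append({"event": "scenario_applied", "scenario": spec.name,
                           "strategy": spec.strategy, "n_replacements": len(events)})
        totals = nutrient_totals(new_records, data.food_table, data.persons)

        models: dict[tuple[str, str], HabitualModel] = {}
        means: dict[tuple[str, str], float] = {}
        cis: dict[tuple[str, str], tuple[float, float]] = {}
        adequacy: list[AdequacyEstimate] = []
        shares: dict[str, float] = {}

        for sex in sexes_present:
            dists = {}
            lam_fixed: dict[str, float] = {}
            for nut in config.nutrients:
                model = fit_habitual_model(totals, data.persons, nut, sex,
                                           min_persons=config.min_persons)
                models[(sex, nut)] = model
                lam_fixed[nut] = model.lam
                dist = habitual_distribution(model, data.persons, totals)
                dists[nut] = dist
                means[(sex, nut)] = dist.summary["mean"]
                if model.sigma_b_truncated:
                    log_events.append({"event": "sigma_b_truncated",
                                       "scenario": spec.name, "strategy": spec.strategy,
                                       "sex": sex, "nutrient": nut})

            ci: dict[str, tuple[float, float]] = {}
            if config.n_boot >= 2:
                ci = bootstrap_ci(
                    totals, data.persons[data.persons["sex"] == sex],
                    lambda d, p: _scenario_stats(
                        d, p, sex, config.nutrients, ear_by_sex[sex],
                        lam_fixed, min_persons=2),
                    n_boot=config.n_boot,
                    seed=_boot_seed(config.master_seed, spec.name, spec.strategy, sex))
            for nut in config.nutrients:
                cis[(sex, nut)] = ci.get(f"habitual_mean_{nut}", (np.nan, np.nan))
                report.add(sex, spec.name, spec.strategy, f"habitual_mean_{nut}",
                           means[(sex, nut)], *cis[(sex, nut)])
            for nut in config.nutrients:
                if nut in ear_by_sex[sex]:
                    prop = proportion_below(dists[nut], ear_by_sex[sex][nut])
                    prop_ci = ci.get(f"prop_below_ear_{nut}", (np.nan, np.nan))
                    adequacy.append(AdequacyEstimate(
                        nutrient=nut, sex=sex, scenario=spec.name,
                        prop_below_ear=prop, ci95=prop_ci))
                    report.add(sex, spec.name, spec.strategy,
                               f"prop_below_ear_{nut}", prop, *prop_ci)
            if "plant_protein_g" in dists and "total_protein_g" in dists:
                shares[sex] = plant_protein_share(dists)
                share_ci = ci.get("plant_protein_share", (np.nan, np.nan))
                report.add(sex, spec.name, spec.strategy, "plant_protein_share",
                           shares[sex], *share_ci)

        fp_day = person_day_footprint(new_records, data.food_table)
        footprints: dict[str, object] = {}
        for sl in ("total", *sexes_present):
            ref = reference_fp.get(sl) if spec.name != "reference" else None
            fp = population_footprint(fp_day, data.persons, sl, spec.name, ref)
            footprints[sl] = fp
            if spec.name == "reference":
                reference_fp[sl] = fp
            for metric, value in fp.as_series().items():
                report.add(sl, spec.name, spec.strategy, metric, value)
            for metric, value in fp.relative_diff_vs_reference.items():
                report.add(sl, spec.name, spec.strategy,
                           f"{metric}_rel_diff_pct", value)
        contributions = group_contributions(new_records, data.food_table, data.persons)

        if config.compute_allocation_cv and spec.name != "reference":
            cv = replicate_allocation_cv(
                data.records, data.food_table, data.mapping, spec,
                n_replicates=config.n_replicates_cv, persons=data.persons)
            allocation_cv[(spec.name, spec.strategy)] = cv
            log_events.append({
                "event": "allocation_cv", "scenario": spec.name,
                "strategy": spec.strategy,
                "cv_total_protein": float(cv["total_protein_g"])})

        results[(spec.name, spec.strategy)] = ScenarioResult(
            spec=spec, models=models, habitual_means=means, habitual_cis=cis,
            adequacy=adequacy, plant_protein_share=shares,
            footprints=footprints, contributions=contributions)

    # CI non-overlap flags versus the reference scenario
    ref = results[("reference", "quantity")]
    for key, res in results.items():
        if key[0] == "reference":
            continue
        for (sex, nut), ci in res.habitual_cis.items():
            ref_ci = ref.habitual_cis.get((sex, nut))
            if ref_ci and np.isfinite(ci[0]) and np.isfinite(ref_ci[0]):
                flag = compare_scenarios(ci, ref_ci)
                report.add(sex, key[0], key[1],
                           f"differs_from_reference_{nut}", float(flag))

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.csv")
        with open(out / "run_log.jsonl", "w") as fh:
            for ev in log_events:
                fh.write(json.dumps(ev) + "\n")
        if config.data_dir is None:
            write_dataset(data, out / "data")

    return PipelineResult(config=config, report=report, scenarios=results,
                          allocation_cv=allocation_cv, log_events=log_events)
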