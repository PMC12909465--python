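"""Usual-intake model: transform selection, variance split, back-transform,
cut-point proportions and bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest

from dietshift import (
    HabitualDistribution, HabitualIntakeError, bootstrap_ci, compare_scenarios,
    fit_habitual_model, habitual_distribution, proportion_below,
)
from conftest import make_persons


def _daily(values_by_person: dict[str, tuple[float, float]]) -> pd.DataFrame:
    rows = [(pid, d, v) for pid, days in values_by_person.items()
            for d, v in zip((1, 2), days)]
    return pd.DataFrame(rows, columns=["person_id", "day_index", "total_protein_g"])


def _persons(ids, sex="female", weights=None, ages=None):
    weights = weights or [1.0] * len(ids)
    ages = ages or [40] * len(ids)
    return make_persons([(p, sex, a, w) for p, a, w in zip(ids, ages, weights)])


class TestFit:
    def test_zero_within_person_difference_gives_sigma_w_zero(self):
        daily = _daily({f"p{i}": (v, v) for i, v in enumerate(
            np.linspace(10, 90, 60))})
        persons = _persons(daily["person_id"].unique())
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1)
        assert model.sigma_w == 0.0
        assert model.sigma_b > 0.0

    def test_all_intakes_equal_is_fully_degenerate(self):
        daily = _daily({f"p{i}": (50.0, 50.0) for i in range(60)})
        persons = _persons(daily["person_id"].unique(),
                           ages=list(range(18, 66)) + list(range(18, 30)))
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1)
        assert model.sigma_b == model.sigma_w == 0.0
        assert model.beta_age == 0.0

    def test_single_day_persons_are_dropped(self):
        daily = _daily({f"p{i}": (40.0 + i, 42.0 + i) for i in range(10)})
        daily = pd.concat([daily, pd.DataFrame(
            [("lone", 1, 50.0)], columns=daily.columns)], ignore_index=True)
        persons = _persons(list(daily["person_id"].unique()))
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1)
        assert model.n_dropped == 1
        assert model.n_persons == 10

    def test_too_few_persons_is_an_error(self):
        daily = _daily({"p1": (40.0, 42.0)})
        persons = _persons(["p1"])
        with pytest.raises(HabitualIntakeError, match="50"):
            fit_habitual_model(daily, persons, "total_protein_g", "female")

    def test_zero_intakes_trigger_shift(self):
        vals = {f"p{i}": (float(i), float(i + 1)) for i in range(60)}  # p0 has a 0
        daily = _daily(vals)
        persons = _persons(daily["person_id"].unique())
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1)
        assert model.shift == 0.5  # half the smallest positive value (1.0)

    def test_recovers_lognormal_truth(self, women_1000):
        """On correctly specified data (lambda=0, sigma_b=0.30, sigma_w=0.50)
        the fitted transform and variance components match the generator."""
        from dietshift import nutrient_totals
        data = women_1000
        totals = nutrient_totals(data.records, data.food_table)
        model = fit_habitual_model(totals, data.persons, "total_protein_g", "female")
        p = data.ground_truth.params.set_index(["nutrient", "sex"]).loc[
            ("total_protein_g", "female")]
        assert model.lam <= 0.10  # near the log transform the data follow
        assert model.sigma_b == pytest.approx(p.sigma_b, rel=0.10)
        assert model.sigma_w == pytest.approx(p.sigma_w, rel=0.10)
        assert model.beta_age == pytest.approx(p.age_slope, abs=0.002)


class TestDistribution:
    def test_no_within_noise_returns_person_means_exactly(self):
        vals = np.linspace(10, 90, 60)
        daily = _daily({f"p{i}": (v, v) for i, v in enumerate(vals)})
        persons = _persons(daily["person_id"].unique())
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1)
        dist = habitual_distribution(model, persons, daily)
        by_person = dict(zip(dist.person_id, dist.values))
        for i, v in enumerate(vals):
            assert by_person[f"p{i}"] == pytest.approx(v, rel=1e-9)

    def test_identity_transform_preserves_weighted_mean_exactly(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(80)]
        daily = _daily({p: tuple(rng.normal(60, 8, 2)) for p in ids})
        weights = list(rng.uniform(0.5, 2.0, len(ids)))
        persons = _persons(ids, weights=weights)
        model = fit_habitual_model(daily, persons, "total_protein_g", "female",
                                   min_persons=1, lambda_grid=(1.0,))
        dist = habitual_distribution(model, persons, daily)
        merged = daily.merge(persons, on="person_id")
        grand = np.average(merged["total_protein_g"], weights=merged["weight_factor"])
        assert dist.summary["mean"] == pytest.approx(grand, rel=1e-9)
        assert np.average(dist.values, weights=dist.weights) == pytest.approx(
            grand, rel=1e-9)

    def test_lognormal_population_mean_matches_closed_form(self, women_1000):
        """lambda = 0 limit: estimated population habitual mean within 2% of
        the generator's analytic mean (exp(mu + sigma_b^2/2) averaged over
        the age trend)."""
        from dietshift import nutrient_totals
        data = women_1000
        totals = nutrient_totals(data.records, data.food_table)
        model = fit_habitual_model(totals, data.persons, "total_protein_g", "female")
        dist = habitual_distribution(model, data.persons, totals)
        p = data.ground_truth.params.set_index(["nutrient", "sex"]).loc[
            ("total_protein_g", "female")]
        assert dist.summary["mean"] == pytest.approx(p.true_mean, rel=0.02)

    def test_habitual_variance_not_larger_than_person_mean_variance(self, women_1000):
        from dietshift import nutrient_totals
        data = women_1000
        totals = nutrient_totals(data.records, data.food_table)
        model = fit_habitual_model(totals, data.persons, "total_protein_g", "female")
        dist = habitual_distribution(model, data.persons, totals)
        person_means = (totals["total_protein_g"].groupby(level="person_id").mean()
                        .loc[dist.person_id].to_numpy())
        w = dist.weights
        def wvar(x):
            m = np.average(x, weights=w)
            return np.average((x - m) ** 2, weights=w)
        assert wvar(dist.values) <= wvar(person_means)


class TestProportionBelow:
    def _normal_dist(self, n=200_000, mean=2.0, sd=0.5, seed=1):
        rng = np.random.default_rng(seed)
        vals = rng.normal(mean, sd, n)
        return HabitualDistribution("x", "female", np.arange(n), vals,
                                    np.ones(n), {})

    def test_matches_normal_cdf(self):
        dist = self._normal_dist()
        # P(N(2.0, 0.5) < 1.4) = Phi(-1.2) = 0.1151
        assert proportion_below(dist, 1.4) == pytest.approx(0.1151, abs=0.01)

    def test_edges_and_monotonicity(self):
        dist = self._normal_dist(n=1000)
        assert proportion_below(dist, float(dist.values.min()) * 0.9) == 0.0
        assert proportion_below(dist, float(dist.values.max()) + 1.0) == 1.0
        ears = [1.0, 1.5, 2.0, 2.5]
        props = [proportion_below(dist, e) for e in ears]
        assert props == sorted(props)

    def test_rejects_nonpositive_ear(self):
        with pytest.raises(HabitualIntakeError):
            proportion_below(self._normal_dist(n=10), 0.0)


class TestBootstrap:
    def test_identical_persons_give_zero_width_interval(self):
        daily = _daily({f"p{i}": (50.0, 60.0) for i in range(20)})
        persons = _persons(daily["person_id"].unique())
        ci = bootstrap_ci(daily, persons,
                          lambda d, p: {"mean": float(d["total_protein_g"].mean())},
                          n_boot=25, seed=3)
        lo, hi = ci["mean"]
        assert lo == hi == 55.0

    def test_default_is_200_resamples(self):
        daily = _daily({f"p{i}": (50.0, 60.0) for i in range(5)})
        persons = _persons(daily["person_id"].unique())
        calls = []
        bootstrap_ci(daily, persons, lambda d, p: calls.append(1) or {"s": 0.0},
                     seed=1)
        assert len(calls) == 200

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        daily = _daily({f"p{i}": tuple(rng.normal(50, 10, 2)) for i in range(30)})
        persons = _persons(daily["person_id"].unique())
        fn = lambda d, p: {"mean": float(d["total_protein_g"].mean())}  # noqa: E731
        assert bootstrap_ci(daily, persons, fn, n_boot=50, seed=9) == \
               bootstrap_ci(daily, persons, fn, n_boot=50, seed=9)

    def test_failing_resamples_are_redrawn_within_budget(self):
        daily = _daily({f"p{i}": (50.0, 60.0) for i in range(20)})
        persons = _persons(daily["person_id"].unique())
        state = {"n": 0}

        def flaky(d, p):
            state["n"] += 1
            if state["n"] == 1:
                raise RuntimeError("one bad resample")
            return {"s": 1.0}

        ci = bootstrap_ci(daily, persons, flaky, n_boot=40, seed=2)
        assert ci["s"] == (1.0, 1.0)


class TestCompareScenarios:
    @pytest.mark.parametrize("a,b,expected", [
        ((1.0, 2.0), (3.0, 4.0), True),
        ((1.0, 3.0), (2.0, 4.0), False),
        ((1.0, 2.0), (1.0, 2.0), False),
    ])
    def test_nonoverlap_flag(self, a, b, expected):
        assert compare_scenarios(a, b) is expected
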