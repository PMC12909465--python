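"""Habitual (usual) intake estimation from two recall days per person.

A one-part measurement-error model for nutrients consumed daily by
everyone: Box-Cox transform the daily intakes (power chosen on a fixed
grid by Gaussian profile likelihood), fit a linear age trend per sex by
weighted least squares, and split the residual variance into a
between-person component sigma_b^2 and a within-person (day-to-day)
component sigma_w^2. The population habitual-intake distribution is then
the back-transformed distribution of the person-level predictor:

* per-person habitual values use variance-matched empirical-Bayes scaling
  of the person-mean residual (factor sigma_b / sqrt(sigma_b^2 +
  sigma_w^2/d)), so their transformed-scale variance equals sigma_b^2 and
  the distribution can be compared directly with cut-off values such as
  the EAR (posterior-mean shrinkage would under-disperse the distribution
  and bias tail proportions);
* the population mean is computed by 30-node Gauss-Hermite integration of
  the inverse transform over N(age trend, sigma_b^2), which is unbiased
  on the original scale and exactly mean-preserving in the linear
  (lambda = 1) case.

Uncertainty is quantified by a stratified person-level bootstrap (both
recall days of a resampled person travel together), 200 iterations by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Box-Cox power grid: 0 (log) to 1 (identity) in steps of 0.05.
LAMBDA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


def standardized_boxcox(y: np.ndarray, lam: float, gm: float) -> np.ndarray:
    """Geometric-mean-standardized Box-Cox transform.

    z = ((y/gm)^lam - 1)/lam, with z = log(y/gm) at lam = 0. The
    standardization makes the transform's derivative equal to 1/gm at the
    (weighted) geometric mean for every lam, so residual variances — and
    hence sigma_b, sigma_w — are directly comparable across the grid, and
    the Box-Cox Jacobian term cancels from the profile likelihood.
    """
    r = np.asarray(y, dtype=float) / gm
    if lam == 0.0:
        return np.log(r)
    return (np.power(r, lam) - 1.0) / lam


def standardized_boxcox_inverse(t: np.ndarray, lam: float, gm: float) -> np.ndarray:
    """Inverse of the standardized transform; a negative base (lam > 0) is
    clamped at 0."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return gm * np.exp(np.minimum(t, 700.0))
    base = lam * t + 1.0
    return gm * np.power(np.maximum(base, 0.0), 1.0 / lam)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(30)


class HabitualIntakeError(ValueError):
    pass


@dataclass
class HabitualModel:
    """Fitted transform + age trend + variance components for one
    (nutrient, sex)."""

    nutrient: str
    sex: str
    lam: float
    gm: float             # weighted geometric mean anchoring the transform
    alpha: float          # transformed-scale intercept at age 40
    beta_age: float       # transformed-scale slope per year of age
    sigma_b: float        # between-person SD, transformed scale
    sigma_w: float        # within-person SD, transformed scale
    shift: float = 0.0    # zero-handling shift added before transforming
    n_persons: int = 0
    n_dropped: int = 0    # persons dropped for having fewer than 2 days
    sigma_b_truncated: bool = False

    def age_fn(self, age: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta_age * (np.asarray(age, dtype=float) - 40.0)


@dataclass
class HabitualDistribution:
    """Population distribution of habitual daily intake for one
    (nutrient, sex): per-person back-transformed values with survey
    weights, plus weighted summary statistics."""

    nutrient: str
    sex: str
    person_id: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    summary: dict[str, float]


@dataclass
class AdequacyEstimate:
    nutrient: str
    sex: str
    scenario: str
    prop_below_ear: float
    ci95: tuple[float, float]

    @property
    def flag_concern(self) -> bool:
        """More than 10% of the population below the EAR indicates a
        potential public health concern."""
        return self.prop_below_ear > 0.10


# ---------------------------------------------------------------------------
# Data marshalling
# ---------------------------------------------------------------------------


def _person_day_values(
    daily_intakes: pd.DataFrame, persons: pd.DataFrame, nutrient: str, sex: str
) -> pd.DataFrame:
    """Long table [person_id, day_index, value, age, weight_factor] for one sex."""
    df = daily_intakes
    if isinstance(df.index, pd.MultiIndex):
        df = df.reset_index()
    if nutrient not in df.columns:
        raise HabitualIntakeError(f"daily intakes lack nutrient column {nutrient!r}")
    sub = persons.loc[persons["sex"] == sex].set_index("person_id")
    age = df["person_id"].map(sub["age"])
    keep = age.notna().to_numpy()
    out = pd.DataFrame({
        "person_id": df["person_id"].to_numpy()[keep],
        "day_index": df["day_index"].to_numpy()[keep],
        "value": df[nutrient].to_numpy()[keep],
        "age": age.to_numpy()[keep],
        "weight_factor": df["person_id"].map(sub["weight_factor"]).to_numpy()[keep],
    })
    return out


def _per_person(codes: np.ndarray, n: int, resid: np.ndarray,
                w: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-person counts, residual means, residual variances (ddof=1) and
    mean weights, via bincount (no pandas groupby)."""
    counts = np.bincount(codes, minlength=n).astype(float)
    sums = np.bincount(codes, weights=resid, minlength=n)
    sumsq = np.bincount(codes, weights=resid**2, minlength=n)
    wsum = np.bincount(codes, weights=w, minlength=n)
    means = sums / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        variances = np.where(counts > 1,
                             (sumsq - sums**2 / counts) / np.maximum(counts - 1, 1),
                             np.nan)
    return counts, means, np.maximum(variances, 0.0), wsum / counts


# ---------------------------------------------------------------------------
# Model fit
# ---------------------------------------------------------------------------


def _wls(z: np.ndarray, age: np.ndarray, w: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Weighted least squares of z on [1, age-40]; returns (alpha, beta, resid)."""
    x = age - 40.0
    sw = w.sum()
    xm = (w * x).sum() / sw
    zm = (w * z).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    beta = 0.0 if sxx <= 0 else float((w * (x - xm) * (z - zm)).sum() / sxx)
    alpha = float(zm - beta * xm)
    return alpha, beta, z - (alpha + beta * x)


def fit_habitual_model(
    daily_intakes: pd.DataFrame,
    persons: pd.DataFrame,
    nutrient: str,
    sex: str,
    *,
    lambda_grid: tuple[float, ...] = LAMBDA_GRID,
    min_persons: int = 50,
    use_weights: bool = True,
) -> HabitualModel:
    """Fit the one-part habitual-intake model for one nutrient and sex.

    The Box-Cox power is chosen from ``lambda_grid`` by maximizing the
    Gaussian profile log-likelihood (with Jacobian) of the transformed
    daily values around the weighted linear age trend. The within-person
    variance is the weighted mean of half the squared day differences of
    the residuals; the between-person variance is the weighted variance of
    person-mean residuals minus its within-person share, truncated at 0.
    Persons with fewer than two recall days are dropped (count recorded).
    """
    data = _person_day_values(daily_intakes, persons, nutrient, sex)
    codes0, uniq0 = pd.factorize(data["person_id"])
    day_counts = np.bincount(codes0, minlength=len(uniq0))
    n_dropped = int((day_counts < 2).sum())
    if n_dropped:
        logger.info("fit %s/%s: dropped %d person(s) with < 2 recall days",
                    nutrient, sex, n_dropped)
        data = data.iloc[np.flatnonzero((day_counts >= 2)[codes0])]
    n_persons = int((day_counts >= 2).sum())
    if n_persons < max(min_persons, 1):
        raise HabitualIntakeError(
            f"need >= {min_persons} persons with >= 2 days for {nutrient}/{sex}, "
            f"got {n_persons}")

    y = data["value"].to_numpy(dtype=float)
    shift = 0.0
    if (y <= 0).any():
        positive = y[y > 0]
        if len(positive) == 0:
            raise HabitualIntakeError(f"all {nutrient}/{sex} intakes are zero")
        shift = 0.5 * float(positive.min())
        logger.info("fit %s/%s: %d non-positive value(s); shifting by %g",
                    nutrient, sex, int((y <= 0).sum()), shift)
        y = y + shift
    age = data["age"].to_numpy(dtype=float)
    w = data["weight_factor"].to_numpy(dtype=float) if use_weights else np.ones_like(y)

    log_y = np.log(y)
    sw = w.sum()
    gm = float(np.exp((w * log_y).sum() / sw))
    best: tuple[float, float, float, float, np.ndarray] | None = None
    for lam in lambda_grid:
        z = standardized_boxcox(y, lam, gm)
        alpha, beta, resid = _wls(z, age, w)
        rss = float((w * resid**2).sum())
        # with the standardized transform the Jacobian term is constant in
        # lambda, so the profile log-likelihood is -0.5 * n * log(RSS/n)
        loglik = np.inf if rss <= 0 else -0.5 * sw * np.log(rss / sw)
        if best is None or loglik > best[0]:
            best = (loglik, lam, alpha, beta, resid)
    _, lam, alpha, beta, resid = best

    codes, uniq = pd.factorize(data["person_id"])
    d_i, pm, pv, pw = _per_person(codes, len(uniq), resid, w)
    sigma_w2 = float((pw * pv).sum() / pw.sum())  # pv = (d1-d2)^2/2 when d = 2
    pm_c = pm - (pw * pm).sum() / pw.sum()
    var_means = float((pw * pm_c**2).sum() / pw.sum())
    within_share = float((pw / d_i).sum() / pw.sum()) * sigma_w2
    sigma_b2 = var_means - within_share
    truncated = sigma_b2 < 0
    if truncated:
        logger.warning("fit %s/%s: sigma_b^2 truncated at 0 (raw %.4g)",
                       nutrient, sex, sigma_b2)
    sigma_b2 = max(0.0, sigma_b2)

    return HabitualModel(
        nutrient=nutrient, sex=sex, lam=float(lam), gm=gm, alpha=alpha, beta_age=beta,
        sigma_b=float(np.sqrt(sigma_b2)), sigma_w=float(np.sqrt(sigma_w2)),
        shift=shift, n_persons=int(n_persons), n_dropped=n_dropped,
        sigma_b_truncated=bool(truncated))


# ---------------------------------------------------------------------------
# Habitual distribution
# ---------------------------------------------------------------------------


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray,
                        qs: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(qs, cum, v)


def habitual_distribution(
    model: HabitualModel,
    persons: pd.DataFrame,
    daily_intakes: pd.DataFrame,
) -> HabitualDistribution:
    """Back-transformed population distribution of habitual intake.

    Per person, the transformed habitual value is the fitted age trend
    plus the variance-matched person-mean residual; the inverse Box-Cox
    clamps a negative base at zero (logged). The summary mean integrates
    the inverse transform over N(age_fn(age), sigma_b^2) with 30-node
    Gauss-Hermite quadrature so the population mean is unbiased on the
    original scale; percentiles are weighted percentiles of the
    per-person values.
    """
    data = _person_day_values(daily_intakes, persons, model.nutrient, model.sex)
    codes0, uniq0 = pd.factorize(data["person_id"])
    day_counts = np.bincount(codes0, minlength=len(uniq0))
    if (day_counts < 2).any():
        data = data.iloc[np.flatnonzero((day_counts >= 2)[codes0])]
    y = data["value"].to_numpy(dtype=float) + model.shift
    z = standardized_boxcox(y, model.lam, model.gm)
    resid = z - model.age_fn(data["age"].to_numpy())
    codes, uniq = pd.factorize(data["person_id"])
    d_i, r_mean, _, _ = _per_person(codes, len(uniq), resid,
                                    np.ones_like(resid))

    first = np.zeros(len(uniq), dtype=int)
    first[codes[::-1]] = np.arange(len(codes))[::-1]  # first row per person
    ages = data["age"].to_numpy(dtype=float)[first]
    weights = data["weight_factor"].to_numpy(dtype=float)[first]

    denom = model.sigma_b**2 + model.sigma_w**2 / d_i
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(denom > 0, model.sigma_b / np.sqrt(denom), 1.0)
    theta = model.age_fn(ages) + factor * r_mean
    if model.lam > 0:
        n_clamped = int((model.lam * theta + 1.0 < 0).sum())
        if n_clamped:
            logger.info("distribution %s/%s: %d value(s) clamped at 0",
                        model.nutrient, model.sex, n_clamped)
    values = standardized_boxcox_inverse(theta, model.lam, model.gm) - model.shift
    values = np.maximum(values, 0.0)

    # population mean: GH integration over the person-effect distribution
    grid = (model.age_fn(ages)[:, None]
            + np.sqrt(2.0) * model.sigma_b * _GH_NODES[None, :])
    person_marginal = ((standardized_boxcox_inverse(grid, model.lam, model.gm)
                        - model.shift)
                       * _GH_WEIGHTS[None, :]).sum(axis=1) / np.sqrt(np.pi)
    mean = float((weights * person_marginal).sum() / weights.sum())

    qs = np.array([0.05, 0.25, 0.50, 0.75, 0.95])
    pvals = _weighted_quantiles(values, weights, qs)
    summary = {"mean": mean, "p5": pvals[0], "p25": pvals[1], "p50": pvals[2],
               "p75": pvals[3], "p95": pvals[4]}
    return HabitualDistribution(
        nutrient=model.nutrient, sex=model.sex,
        person_id=np.asarray(uniq), values=values, weights=weights,
        summary=summary)


def proportion_below(distribution: HabitualDistribution, ear: float) -> float:
    """Survey-weighted fraction of habitual values strictly below the EAR
    (the cut-point method)."""
    if not ear > 0:
        raise HabitualIntakeError("ear must be > 0")
    w = distribution.weights
    return float(w[distribution.values < ear].sum() / w.sum())


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def resample_persons(
    daily_intakes: pd.DataFrame,
    persons: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified bootstrap resample: persons drawn with replacement
    within sex strata; both recall days travel with the person. Resampled
    copies get fresh unique ids."""
    df = daily_intakes
    if isinstance(df.index, pd.MultiIndex):
        df = df.reset_index()
    codes, uniq = pd.factorize(df["person_id"])
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=len(uniq))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    pos_of = {pid: i for i, pid in enumerate(uniq)}

    person_frames = []
    take_parts: list[np.ndarray] = []
    id_parts: list[np.ndarray] = []
    next_id = 0
    for sex in persons["sex"].unique():
        stratum = persons[persons["sex"] == sex]
        draw = rng.integers(0, len(stratum), size=len(stratum))
        picked = stratum.iloc[draw].copy()
        new_ids = np.arange(next_id, next_id + len(picked))
        next_id += len(picked)
        picked["person_id"] = new_ids
        person_frames.append(picked)
        src = np.array([pos_of.get(p, -1) for p in stratum["person_id"].to_numpy()[draw]])
        present = src >= 0
        lengths = counts[src[present]]
        starts = offsets[src[present]]
        total = int(lengths.sum())
        flat = (np.repeat(starts, lengths)
                + np.arange(total)
                - np.repeat(np.cumsum(lengths) - lengths, lengths))
        take_parts.append(order[flat])
        id_parts.append(np.repeat(new_ids[present], lengths))
    new_persons = pd.concat(person_frames, ignore_index=True)[
        ["person_id", "sex", "age", "weight_factor"]]
    resampled = df.iloc[np.concatenate(take_parts)].copy()
    resampled["person_id"] = np.concatenate(id_parts)
    return resampled, new_persons


def bootstrap_ci(
    daily_intakes: pd.DataFrame,
    persons: pd.DataFrame,
    pipeline_fn: Callable[[pd.DataFrame, pd.DataFrame], Mapping[str, float]],
    n_boot: int = 200,
    seed: int = 0,
    max_redraw_frac: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap 95% CIs of the statistics pipeline_fn computes.

    pipeline_fn(daily_intakes, persons) must refit whatever it estimates
    and return a mapping statistic-name -> value. Persons are resampled
    with replacement within sex strata; a resample on which pipeline_fn
    raises is redrawn (at most max_redraw_frac x n_boot redraws).
    Deterministic given seed.
    """
    if n_boot < 2:
        raise HabitualIntakeError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    stats: list[Mapping[str, float]] = []
    max_redraws = int(np.ceil(max_redraw_frac * n_boot))
    redraws = 0
    while len(stats) < n_boot:
        d, p = resample_persons(daily_intakes, persons, rng)
        try:
            stats.append(dict(pipeline_fn(d, p)))
        except Exception:  # noqa: BLE001 - any pipeline failure triggers a redraw
            redraws += 1
            if redraws > max_redraws:
                raise HabitualIntakeError(
                    f"bootstrap exceeded {max_redraws} redraws") from None
    if redraws:
        logger.info("bootstrap: %d resample(s) redrawn", redraws)
    frame = pd.DataFrame(stats)
    lo = frame.quantile(0.025)
    hi = frame.quantile(0.975)
    return {k: (float(lo[k]), float(hi[k])) for k in frame.columns}


def compare_scenarios(
    ci_a: tuple[float, float], ci_b: tuple[float, float]
) -> bool:
    """True ("different") iff the two 95% CIs are disjoint."""
    (a_lo, a_hi), (b_lo, b_hi) = ci_a, ci_b
    return a_hi < b_lo or b_hi < a_lo
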