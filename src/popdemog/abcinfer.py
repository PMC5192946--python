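"""Rejection ABC: model choice, parameter posteriors, predictive checks.

The reference table for each candidate model pairs prior draws with the
multilocus summary vector of a dataset simulated at the observed design
(sample sizes and locus lengths).  Rejection keeps the tolerance fraction of
rows nearest the observed summaries under a Euclidean distance after robust
(median-absolute-deviation) standardization pooled across models; model
posterior probabilities are the per-model shares of the accepted set, and
parameter posteriors are the accepted draws of each model.  Point estimates
are kernel-density modes with 95% highest-posterior-density intervals.

Priors are uniform or log-uniform per parameter.  The population mutation
parameter is specified per site ("theta_site"); per-locus thetas scale with
locus length.  Times simulated in coalescent units convert to the
mutation-scaled times of isolation-with-migration reporting (t = T*mu) via
``mutation_scaled_time`` and on to years via ``years_from_scaled``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalsim import Demography, simulate_dataset
from .errors import ConfigError, EstimationError, PopdemogError
from .seqdata import SiteMatrix
from .sumstats import (
    ABC_SUMMARY_NAMES,
    PAIR_SUMMARY_NAMES,
    dataset_summaries,
    pair_summaries,
)

SINGLE_POP_MODELS = ("SNM", "EXP", "BOT", "BOT_EXP")


@dataclass(frozen=True)
class Prior:
    """Uniform or log-uniform prior on one scalar parameter."""

    kind: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "log-uniform"):
            raise ConfigError(f"unknown prior kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ConfigError(f"prior needs lower < upper, got [{self.lower}, {self.upper}]")
        if self.kind == "log-uniform" and self.lower <= 0:
            raise ConfigError("log-uniform prior needs lower > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, size=n)
        return np.exp(rng.uniform(math.log(self.lower), math.log(self.upper), size=n))


def sample_prior(
    priors: dict[str, Prior], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    if n < 1:
        raise ConfigError("need n >= 1 prior draws")
    return pd.DataFrame({name: p.sample(n, rng) for name, p in priors.items()})


def default_priors(model_id: str) -> dict[str, Prior]:
    """Package-default priors for the five demographic models.

    theta_site spans the diversity range typical of nuclear loci in outcrossing
    plants (per-site pi of order 1e-3); growth rates, size-change times and
    severities cover histories resolvable with a handful of loci.
    """
    theta = Prior("log-uniform", 5e-4, 2e-2)
    if model_id == "SNM":
        return {"theta_site": theta}
    if model_id == "EXP":
        return {"theta_site": theta, "growth_g": Prior("uniform", 0.0, 20.0)}
    if model_id == "BOT":
        return {
            "theta_site": theta,
            "t_b": Prior("uniform", 0.0, 2.0),
            "severity": Prior("log-uniform", 0.01, 1.0),
        }
    if model_id == "BOT_EXP":
        return {
            "theta_site": theta,
            "t_b": Prior("uniform", 0.0, 2.0),
            "severity": Prior("log-uniform", 0.01, 1.0),
            "growth_g": Prior("uniform", 0.0, 20.0),
        }
    if model_id == "IM2":
        return {
            "theta1_site": theta,
            "theta2_site": theta,
            "thetaA_site": theta,
            "t_split": Prior("uniform", 0.0, 2.0),
            "m12": Prior("uniform", 0.0, 5.0),
            "m21": Prior("uniform", 0.0, 5.0),
        }
    raise ConfigError(f"unknown model {model_id!r}")


@dataclass
class StudyDesign:
    """Sample sizes and loci of the observed dataset, mirrored in simulations."""

    n: int | tuple[int, int]
    loci: list[tuple[str, int]]  # (locus_id, L in bp)

    @property
    def mean_L(self) -> float:
        return float(np.mean([L for _, L in self.loci]))

    def sim_loci(self) -> list[tuple[str, float, int]]:
        """(locus_id, theta_scale, L) with length-proportional theta."""
        mL = self.mean_L
        return [(lid, L / mL, L) for lid, L in self.loci]


def demography_from_params(
    model_id: str, params: dict[str, float], mean_L: float
) -> Demography:
    """Map per-site prior draws to a per-locus Demography."""
    if model_id in SINGLE_POP_MODELS:
        return Demography(
            model_id=model_id,
            theta0=params["theta_site"] * mean_L,
            growth_g=params.get("growth_g", 0.0),
            t_b=params.get("t_b", 0.0),
            severity=params.get("severity", 1.0),
        )
    if model_id == "IM2":
        th1 = params["theta1_site"] * mean_L
        return Demography(
            model_id="IM2",
            theta0=th1,
            theta1=th1,
            theta2=params["theta2_site"] * mean_L,
            thetaA=params["thetaA_site"] * mean_L,
            t_split=params["t_split"],
            m12=params.get("m12", 0.0),
            m21=params.get("m21", 0.0),
        )
    raise ConfigError(f"unknown model {model_id!r}")


@dataclass
class ReferenceTable:
    model_id: str
    params: pd.DataFrame
    summaries: pd.DataFrame

    @property
    def n_sims(self) -> int:
        return len(self.params)


def _simulate_summaries(
    model_id: str, params: dict[str, float], design: StudyDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    d = demography_from_params(model_id, params, design.mean_L)
    if model_id == "IM2":
        n1, n2 = design.n  # type: ignore[misc]
        mats = simulate_dataset(d, (n1, n2), design.sim_loci(), rng)
        rowsA = [np.arange(n1)] * len(mats)
        rowsB = [np.arange(n1, n1 + n2)] * len(mats)
        return pair_summaries(mats, rowsA, rowsB)
    mats = simulate_dataset(d, int(design.n), design.sim_loci(), rng)
    return dataset_summaries(mats)


def build_reference_table(
    model_id: str,
    priors: dict[str, Prior],
    design: StudyDesign,
    n_sims: int,
    rng: np.random.Generator,
) -> ReferenceTable:
    """Simulate ``n_sims`` prior draws and their summary vectors."""
    draws = sample_prior(priors, n_sims, rng)
    names = PAIR_SUMMARY_NAMES if model_id == "IM2" else ABC_SUMMARY_NAMES
    out = np.empty((n_sims, len(names)))
    records = draws.to_dict("records")
    for i, rec in enumerate(records):
        out[i] = _simulate_summaries(model_id, rec, design, rng)
    return ReferenceTable(
        model_id=model_id,
        params=draws,
        summaries=pd.DataFrame(out, columns=list(names)),
    )


def observed_summaries(matrices: Sequence[SiteMatrix]) -> pd.Series:
    return pd.Series(dataset_summaries(matrices), index=list(ABC_SUMMARY_NAMES))


@dataclass
class ABCResult:
    model_posteriors: dict[str, float]
    accepted: dict[str, pd.DataFrame]
    modes: dict[str, dict[str, float]]
    hpd95: dict[str, dict[str, tuple[float, float]]]
    tolerance: float
    n_accepted: int
    observed: pd.Series
    predictive_quantiles: dict[str, float] | None = None


def _robust_scale(pooled: np.ndarray) -> np.ndarray:
    med = np.median(pooled, axis=0)
    mad = np.median(np.abs(pooled - med), axis=0)
    sd = pooled.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


def rejection_sample(
    observed: pd.Series,
    tables: Sequence[ReferenceTable],
    tolerance: float,
    min_posterior_draws: int = 50,
) -> ABCResult:
    """Rejection step: nearest tolerance-fraction of pooled simulations.

    Model posteriors are the per-model shares of the accepted set; per-model
    parameter posteriors (mode + 95% HPD) are reported whenever a model
    retains at least ``min_posterior_draws`` accepted rows.
    """
    if not 0 < tolerance <= 1:
        raise PopdemogError("tolerance must be in (0, 1]")
    names = list(tables[0].summaries.columns)
    for t in tables:
        if list(t.summaries.columns) != names:
            raise PopdemogError("summary names differ across reference tables")
    pooled = np.vstack([t.summaries.to_numpy() for t in tables])
    model_of_row = np.concatenate(
        [np.full(t.n_sims, i) for i, t in enumerate(tables)]
    )
    row_in_model = np.concatenate([np.arange(t.n_sims) for t in tables])
    scale = _robust_scale(pooled)
    obs = observed.reindex(names).to_numpy(dtype=float)
    dist = np.sqrt((((pooled - obs) / scale) ** 2).sum(axis=1))
    n_acc = max(1, int(round(tolerance * pooled.shape[0])))
    order = np.argsort(dist, kind="stable")[:n_acc]

    posteriors: dict[str, float] = {}
    accepted: dict[str, pd.DataFrame] = {}
    modes: dict[str, dict[str, float]] = {}
    hpds: dict[str, dict[str, tuple[float, float]]] = {}
    for i, t in enumerate(tables):
        rows = row_in_model[order[model_of_row[order] == i]]
        posteriors[t.model_id] = rows.size / n_acc
        acc = t.params.iloc[rows].reset_index(drop=True)
        accepted[t.model_id] = acc
        if rows.size >= min_posterior_draws:
            modes[t.model_id] = {
                c: posterior_mode(acc[c].to_numpy()) for c in acc.columns
            }
            hpds[t.model_id] = {
                c: hpd_interval(acc[c].to_numpy()) for c in acc.columns
            }
    return ABCResult(
        model_posteriors=posteriors,
        accepted=accepted,
        modes=modes,
        hpd95=hpds,
        tolerance=tolerance,
        n_accepted=n_acc,
        observed=observed,
    )


def posterior_mode(samples: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a Gaussian-kernel density (Silverman bandwidth, 512-point grid).

    Ties between equal density maxima resolve to the lower value.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 50:
        raise EstimationError(f"posterior mode needs >= 50 samples, got {samples.size}")
    lo, hi = samples.min(), samples.max()
    if lo == hi:
        return float(lo)
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(level * n) sorted samples."""
    samples = np.sort(np.asarray(samples, dtype=float))
    n = samples.size
    if n < 50:
        raise EstimationError(f"HPD interval needs >= 50 samples, got {n}")
    k = int(math.ceil(level * n))
    if k >= n:
        return float(samples[0]), float(samples[-1])
    widths = samples[k - 1 :] - samples[: n - k + 1]
    i = int(np.argmin(widths))
    return float(samples[i]), float(samples[i + k - 1])


def posterior_predictive_check(
    result: ABCResult,
    model_id: str,
    design: StudyDesign,
    n_rep: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Quantile of each observed summary within its posterior predictive.

    Resamples accepted parameter vectors with replacement, simulates a
    dataset for each, and reports the fraction of predictive values at or
    below the observed one; values near 0 or 1 flag summaries the fitted
    model fails to reproduce.
    """
    if n_rep < 1:
        raise EstimationError("posterior predictive check needs n_rep >= 1")
    acc = result.accepted.get(model_id)
    if acc is None or acc.empty:
        raise EstimationError(f"no accepted draws for model {model_id!r}")
    idx = rng.integers(acc.shape[0], size=n_rep)
    names = list(result.observed.index)
    sims = np.empty((n_rep, len(names)))
    for r, i in enumerate(idx):
        sims[r] = _simulate_summaries(model_id, acc.iloc[int(i)].to_dict(), design, rng)
    obs = result.observed.to_numpy(dtype=float)
    quantiles = (sims <= obs).mean(axis=0)
    result.predictive_quantiles = dict(zip(names, quantiles.tolist()))
    return result.predictive_quantiles


def fit_im2(
    matrices: Sequence[SiteMatrix],
    rowsA: Sequence[np.ndarray],
    rowsB: Sequence[np.ndarray],
    priors: dict[str, Prior],
    n_sims: int,
    tolerance: float,
    rng: np.random.Generator,
    table: ReferenceTable | None = None,
) -> ABCResult:
    """Joint posterior over IM2 parameters for one population pair.

    The observed summary vector combines per-population reductions with
    between-population divergence.  Accepted draws carry derived columns:
    the population migration rates 2*N*M = m/2 (and m/2 * theta2/theta1 for
    the second deme) and the mutation-scaled split time t = t_split * theta1
    per locus of mean length.  ``table`` lets callers reuse a prebuilt
    reference table.
    """
    nA = {len(r) for r in rowsA}
    nB = {len(r) for r in rowsB}
    if len(nA) != 1 or len(nB) != 1:
        raise PopdemogError("per-locus sample sizes must be constant within population")
    n1, n2 = nA.pop(), nB.pop()
    if n1 == 0 or n2 == 0:
        raise PopdemogError("fit_im2 needs exactly 2 non-empty populations")
    design = StudyDesign(
        n=(n1, n2), loci=[(f"locus{i}", m.L) for i, m in enumerate(matrices)]
    )
    obs = pd.Series(
        pair_summaries(matrices, rowsA, rowsB), index=list(PAIR_SUMMARY_NAMES)
    )
    if table is None:
        table = build_reference_table("IM2", priors, design, n_sims, rng)
    result = rejection_sample(obs, [table], tolerance)
    acc = result.accepted["IM2"]
    if not acc.empty:
        acc = acc.assign(
            two_NM_12=acc["m12"] / 2.0,
            two_NM_21=acc["m21"] / 2.0 * acc["theta2_site"] / acc["theta1_site"],
            t_mut=acc["t_split"] * acc["theta1_site"] * design.mean_L,
        )
        result.accepted["IM2"] = acc
        if acc.shape[0] >= 50:
            for c in ("two_NM_12", "two_NM_21", "t_mut"):
                result.modes["IM2"][c] = posterior_mode(acc[c].to_numpy())
                result.hpd95["IM2"][c] = hpd_interval(acc[c].to_numpy())
    return result


def population_migration_rate(theta: float, m: float) -> float:
    """2*N*M = 0.5 * theta * m for mutation-scaled theta and m = M/mu."""
    return 0.5 * theta * m


def mutation_scaled_time(t_coal: float, theta_ref: float) -> float:
    """t = T*mu from a time in 4N0 units: t_mut = t_coal * theta_ref."""
    return t_coal * theta_ref


@dataclass
class TimeScale:
    """Constants converting mutation-scaled times to years.

    ``mu_per_locus_year`` is the locus mutation rate per year; ``theta_ref``
    the per-locus theta fixing the coalescent time unit; ``generation_years``
    is carried as metadata for reporting.
    """

    mu_per_locus_year: float
    theta_ref: float = 1.0
    generation_years: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_per_locus_year <= 0 or self.theta_ref <= 0 or self.generation_years <= 0:
            raise ConfigError("time-scale constants must be > 0")


def years_from_scaled(t_mut: float, ts: TimeScale) -> float:
    """Absolute time in years, T = t / mu."""
    return t_mut / ts.mu_per_locus_year


def coalescent_units(t_mut: float, ts: TimeScale) -> float:
    """Mutation-scaled time in 4N0 units, t_coal = t / theta_ref."""
    return t_mut / ts.theta_ref


def theta_trajectory(
    model_id: str,
    accepted: pd.DataFrame,
    time_grid: np.ndarray,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> pd.DataFrame:
    """Posterior quantiles of the per-site theta trajectory theta(t).

    Times are in 4N0 units looking backwards; each accepted draw contributes
    its deterministic size history.
    """
    if model_id not in SINGLE_POP_MODELS:
        raise ConfigError("theta trajectories are defined for single-population models")
    t = np.asarray(time_grid, dtype=float)
    th0 = accepted["theta_site"].to_numpy()[:, None]
    g = accepted["growth_g"].to_numpy()[:, None] if "growth_g" in accepted else 0.0
    tb = accepted["t_b"].to_numpy()[:, None] if "t_b" in accepted else np.inf
    sev = accepted["severity"].to_numpy()[:, None] if "severity" in accepted else 1.0
    if model_id == "SNM":
        traj = np.broadcast_to(th0, (th0.shape[0], t.size)).copy()
    elif model_id == "EXP":
        traj = th0 * np.exp(-g * t[None, :])
    elif model_id == "BOT":
        traj = np.where(t[None, :] < tb, th0, th0 / sev)
    else:  # BOT_EXP
        traj = np.where(t[None, :] < tb, th0 * np.exp(-g * t[None, :]), th0 / sev)
    qs = np.quantile(traj, quantiles, axis=0)
    out = pd.DataFrame({"t": t})
    for q, row in zip(quantiles, qs):
        out[f"q{q}"] = row
    return out
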