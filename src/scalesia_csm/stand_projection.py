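"""Stochastic projection of stand-level carbon (Mg C/ha) over a 10-year horizon.

The carbon sequestration model composes, on a common quarterly time grid:

* a per-tree carbon trajectory (height curve -> estimated DBH -> allometric
  dry mass -> carbon), for a tree that survives;
* the population-level survival curve of the logistic mixed model, entering
  as the expected surviving fraction (a continuous projection rather than
  Bernoulli thinning of individual trees);
* the planting density (530 trees/ha by default, the mean across the
  restoration sites);
* a multiplicative mean-one geometric (log-normal) random walk whose standard
  deviation at the horizon equals the configured noise level (20% by
  default), standing in for unmodelled stochastic events such as bad years or
  spontaneous regeneration.

Replicates differ only in their noise path; the mean and its standard error
(and the replicate SD, the quantity the uncertainty bands are drawn from) are
reported per time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .growth_allometry import (
    BREAST_HEIGHT_CM,
    DEFAULT_ALLOMETRY,
    AllometryParams,
    DbhModelFit,
    estimate_dbh,
    tree_carbon,
)
from .survival_model import SurvivalFixedEffects, predict_survival, time_grid

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionConfig",
    "ProjectionResult",
    "generating_dbh_fit",
    "per_tree_trajectory",
    "brownian_noise_path",
    "all_data_contrast",
    "survival_series",
    "project_stand",
    "compare_treatments",
]

ALL_DATA = "all-data"


@dataclass(frozen=True)
class ProjectionConfig:
    """Settings of the stand projection."""

    density: float = 530.0
    horizon: float = 10.0
    step: float = 0.25
    noise_level: float = 0.20
    n_replicates: int = 500
    treatment: str = ALL_DATA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0.0 <= self.noise_level < 1.0:
            raise ValueError("noise_level must lie in [0, 1)")
        if self.horizon <= 0 or self.step <= 0:
            raise ValueError("horizon and step must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ProjectionResult:
    """Time series of stand carbon with replicate-based uncertainty."""

    times: np.ndarray
    mean_carbon: np.ndarray
    se_carbon: np.ndarray
    sd_carbon: np.ndarray
    replicate_trajectories: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_carbon = np.asarray(self.mean_carbon, dtype=float)
        self.se_carbon = np.asarray(self.se_carbon, dtype=float)
        self.sd_carbon = np.asarray(self.sd_carbon, dtype=float)
        n = len(self.times)
        if not (len(self.mean_carbon) == len(self.se_carbon) == len(self.sd_carbon) == n):
            raise ValueError("series lengths are inconsistent")
        if np.any(self.mean_carbon < 0) or np.any(self.se_carbon < 0):
            raise ValueError("carbon series must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_years": self.times,
                "mean_mg_c_per_ha": self.mean_carbon,
                "se_mg_c_per_ha": self.se_carbon,
                "sd_mg_c_per_ha": self.sd_carbon,
            }
        )


def generating_dbh_fit(growth) -> DbhModelFit:
    """DbhModelFit view of a GrowthParams generating model (no fitting)."""
    return DbhModelFit(
        intercept=growth.dbh_intercept,
        age_coef=growth.dbh_age_coef,
        height_coef=growth.dbh_height_coef,
        residual_sd=0.0,
    )


def per_tree_trajectory(
    growth,
    dbh_fit: DbhModelFit,
    allom: AllometryParams = DEFAULT_ALLOMETRY,
    horizon: float = 10.0,
    step: float = 0.25,
    initial_height: float = 35.52,
) -> np.ndarray:
    """Cumulative aboveground carbon (kg C) of one surviving tree over time.

    Heights follow the median growth curve; trees below breast height carry
    DBH 0 (and hence no measurable carbon) by convention, so the series
    starts at 0 for a 35 cm seedling.
    """
    times = time_grid(horizon, step)
    heights = growth.mean_height(times, init_height=initial_height)
    dbh = np.where(
        heights >= BREAST_HEIGHT_CM, estimate_dbh(dbh_fit, times, heights), 0.0
    )
    return tree_carbon(dbh, allom)


def brownian_noise_path(n_steps: int, noise_level: float, rng) -> np.ndarray:
    """Mean-one multiplicative log-normal random-walk factors.

    Returns ``n_steps + 1`` factors with factor(0) = 1.  Log-increments are
    i.i.d. normal with a -sigma^2/2 drift correction; the increment variance
    is scaled so the factor's standard deviation at the final step equals
    ``noise_level`` (total log-variance log(1 + noise_level^2)).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 <= noise_level < 1.0:
        raise ValueError("noise_level must lie in [0, 1)")
    if noise_level == 0.0:
        return np.ones(n_steps + 1)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    var_total = np.log1p(noise_level**2)
    var_step = var_total / n_steps
    increments = rng.normal(-0.5 * var_step, np.sqrt(var_step), size=n_steps)
    return np.concatenate([[1.0], np.exp(np.cumsum(increments))])


def all_data_contrast(
    fixed: SurvivalFixedEffects, allocation: Mapping[str, float] | None = None
) -> float:
    """Arm-size-weighted mean treatment contrast for the full-dataset scenario."""
    if allocation is None:
        from .synthetic_cohort import DEFAULT_ALLOCATION

        allocation = DEFAULT_ALLOCATION
    total = sum(allocation.values())
    return sum(
        w * fixed.treatment_contrasts[t] for t, w in allocation.items() if t in fixed.treatment_contrasts
    ) / total


def survival_series(
    fixed: SurvivalFixedEffects,
    treatment: str,
    times: np.ndarray,
    allocation: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Population-level surviving fraction at each time point."""
    times = np.asarray(times, dtype=float)
    if treatment == ALL_DATA:
        cbar = all_data_contrast(fixed, allocation)
        return expit(fixed.intercept + cbar + fixed.age_slope * times)
    return np.asarray(predict_survival(fixed, treatment, times))


def project_stand(
    config: ProjectionConfig,
    survival_fixed: SurvivalFixedEffects,
    tree_curve: np.ndarray,
    allocation: Mapping[str, float] | None = None,
    keep_replicates: bool = False,
) -> ProjectionResult:
    """Project stand carbon: density x survival x per-tree carbon x noise.

    ``tree_curve`` (kg C per surviving tree) must be defined on the grid
    implied by the config's horizon and step; a length mismatch raises an
    alignment error.  Carbon is reported in Mg C/ha.  Each replicate draws an
    independent noise path from a substream spawned off the master seed.
    """
    times = time_grid(config.horizon, config.step)
    tree_curve = np.asarray(tree_curve, dtype=float)
    if tree_curve.shape != times.shape:
        raise ValueError(
            f"alignment error: tree curve has {tree_curve.shape[0]} points but the "
            f"time grid has {times.shape[0]}"
        )
    surv = survival_series(survival_fixed, config.treatment, times, allocation)
    base = config.density * surv * tree_curve / 1000.0  # kg -> Mg

    n_rep = config.n_replicates
    if config.noise_level == 0.0:
        # replicates are identical: the projection is exactly the product
        reps = np.tile(base, (n_rep, 1))
        mean = base.copy()
        sd = np.zeros_like(base)
    else:
        children = np.random.SeedSequence(config.seed).spawn(n_rep)
        reps = np.empty((n_rep, len(times)))
        for i, child in enumerate(children):
            factors = brownian_noise_path(
                len(times) - 1, config.noise_level, np.random.default_rng(child)
            )
            reps[i] = base * factors
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros_like(mean)
    se = sd / np.sqrt(n_rep)
    return ProjectionResult(
        times=times,
        mean_carbon=mean,
        se_carbon=se,
        sd_carbon=sd,
        replicate_trajectories=reps if keep_replicates else None,
    )


def compare_treatments(
    config: ProjectionConfig,
    survival_fixed: SurvivalFixedEffects,
    tree_curve: np.ndarray,
    treatments: Sequence[str] | None = None,
    allocation: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Horizon-end carbon per treatment plus the full-dataset scenario.

    All rows share the same master seed, so the noise paths are common random
    numbers and differences between rows are purely the survival contrasts.
    """
    if treatments is None:
        treatments = sorted(survival_fixed.treatment_contrasts)
    rows = []
    for treatment in [*treatments, ALL_DATA]:
        cfg = ProjectionConfig(
            density=config.density,
            horizon=config.horizon,
            step=config.step,
            noise_level=config.noise_level,
            n_replicates=config.n_replicates,
            treatment=treatment,
            seed=config.seed,
        )
        result = project_stand(cfg, survival_fixed, tree_curve, allocation)
        rows.append(
            {
                "treatment": treatment,
                "horizon_years": config.horizon,
                "mean_mg_c_per_ha": result.mean_carbon[-1],
                "se_mg_c_per_ha": result.se_carbon[-1],
                "sd_mg_c_per_ha": result.sd_carbon[-1],
            }
        )
    return pd.DataFrame(rows)
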