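"""Tree-level growth and allometry.

Multi-stem trunks are collapsed to one equivalent diameter at breast height
(DBH) by summing the stem cross-sectional areas.  DBH itself is estimated as a
linear function of plant age and height, fitted on the subsample of trees whose
trunk circumference was actually measured, and then applied to every monitoring
record.  Dry biomass is split into a woody compartment (trunk + branches) and a
foliage compartment using two power laws in DBH^2, and converted to elemental
carbon by a fixed carbon fraction.

Units: DBH and height in cm, age in years, dry mass in kg, carbon in kg C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Breast height in cm.  Plants shorter than this carry DBH 0 by convention.
BREAST_HEIGHT_CM = 137.0

__all__ = [
    "BREAST_HEIGHT_CM",
    "AllometryParams",
    "DbhModelFit",
    "aggregate_multistem",
    "dbh_from_circumferences",
    "extract_dbh_subsample",
    "fit_dbh_model",
    "estimate_dbh",
    "dry_mass",
    "tree_carbon",
]


@dataclass(frozen=True)
class AllometryParams:
    """Coefficients of the two dry-mass power laws plus the carbon fraction.

    ``woody = woody_a * (dbh^2) ** woody_b`` and likewise for foliage, with
    DBH in cm and mass in kg.  ``carbon_fraction`` is the proportion of dry
    biomass that is elemental carbon; values for tropical broad-leaved trees
    cluster in 0.47-0.49, and a value outside that band is accepted with a
    warning.
    """

    woody_a: float = 0.01540
    woody_b: float = 1.60906
    foliage_a: float = 0.01769
    foliage_b: float = 0.77946
    carbon_fraction: float = 0.48

    def __post_init__(self) -> None:
        for name in ("woody_a", "woody_b", "foliage_a", "foliage_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must lie strictly in (0, 1)")
        if not 0.47 <= self.carbon_fraction <= 0.49:
            logger.warning(
                "carbon_fraction %.3f is outside the plausible 0.47-0.49 band "
                "for tropical broad-leaved species",
                self.carbon_fraction,
            )


DEFAULT_ALLOMETRY = AllometryParams()


@dataclass(frozen=True)
class DbhModelFit:
    """OLS fit of DBH ~ age + height, with fidelity correlations.

    ``r_age`` / ``r_height`` are Pearson correlations between model-estimated
    DBH and each predictor, computed over whatever record set was supplied at
    fit time (the full monitoring table when available).
    """

    intercept: float
    age_coef: float
    height_coef: float
    residual_sd: float
    r_age: float = field(default=float("nan"))
    r_height: float = field(default=float("nan"))
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for r in (self.r_age, self.r_height):
            if not math.isnan(r) and not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")


def aggregate_multistem(stem_radii) -> float:
    """Collapse several stems to one equivalent DBH (cm).

    Cross-sectional areas ``pi * r_i^2`` are summed, divided by pi, and the
    square root taken to obtain a single radius representing the whole tree;
    the result is ``2 * sqrt(sum r_i^2)``.
    """
    radii = np.asarray(stem_radii, dtype=float)
    if radii.size == 0:
        raise ValueError("invalid measurement: need at least one stem radius")
    if np.any(radii <= 0) or not np.all(np.isfinite(radii)):
        raise ValueError("invalid measurement: stem radii must be positive and finite")
    return float(2.0 * np.sqrt(np.sum(radii**2)))


def dbh_from_circumferences(circumferences) -> float:
    """Equivalent DBH (cm) from per-stem circumferences at breast height."""
    circs = np.asarray(circumferences, dtype=float)
    radii = circs / (2.0 * np.pi)
    return aggregate_multistem(radii)


def extract_dbh_subsample(records: pd.DataFrame) -> pd.DataFrame:
    """Pull the (plant_id, age, height, dbh) subsample from a monitoring table.

    Rows qualify when they carry a non-empty ``stem_circumferences`` entry
    (the trees whose trunks were actually taped at breast height).
    """
    has_stems = records["stem_circumferences"].map(
        lambda s: s is not None and not (isinstance(s, float) and np.isnan(s)) and len(s) > 0
    )
    sub = records.loc[has_stems, ["plant_id", "age", "height", "stem_circumferences"]].copy()
    if sub.empty:
        raise ValueError("no records carry stem circumference measurements")
    sub["dbh"] = sub["stem_circumferences"].map(dbh_from_circumferences)
    return sub.drop(columns="stem_circumferences").reset_index(drop=True)


def fit_dbh_model(
    subsample: pd.DataFrame, records: pd.DataFrame | None = None
) -> DbhModelFit:
    """Fit DBH ~ age + height by ordinary least squares.

    ``subsample`` needs columns age, height and dbh.  When the full monitoring
    table ``records`` is given, the fidelity correlations r_age / r_height are
    evaluated between the model-estimated DBH and each predictor over every
    living record; otherwise over the subsample itself.
    """
    required = {"age", "height", "dbh"}
    missing = required - set(subsample.columns)
    if missing:
        raise ValueError(f"subsample lacks columns: {sorted(missing)}")
    if len(subsample) < 3:
        raise ValueError("need at least 3 observations to fit the DBH model")

    X = sm.add_constant(subsample[["age", "height"]].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: age and height are collinear or constant")
    y = subsample["dbh"].to_numpy(float)
    res = sm.OLS(y, X).fit()
    residual_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0

    fit = DbhModelFit(
        intercept=float(res.params[0]),
        age_coef=float(res.params[1]),
        height_coef=float(res.params[2]),
        residual_sd=residual_sd,
        n_obs=len(subsample),
    )

    frame = subsample if records is None else records
    if records is not None:
        frame = records.loc[records["alive"].astype(bool) & records["height"].notna()]
    age = frame["age"].to_numpy(float)
    height = frame["height"].to_numpy(float)
    est = estimate_dbh(fit, age, height)
    r_age = float(np.corrcoef(est, age)[0, 1])
    r_height = float(np.corrcoef(est, height)[0, 1])
    return DbhModelFit(
        intercept=fit.intercept,
        age_coef=fit.age_coef,
        height_coef=fit.height_coef,
        residual_sd=fit.residual_sd,
        r_age=r_age,
        r_height=r_height,
        n_obs=fit.n_obs,
    )


def estimate_dbh(fit: DbhModelFit, age, height):
    """Linear DBH prediction in cm, floored at 0.

    The fitted plane can dip below zero for young, short plants; negative
    predictions are clamped rather than raised.
    """
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    if np.any(height <= 0):
        raise ValueError("height must be > 0")
    pred = fit.intercept + fit.age_coef * age + fit.height_coef * height
    out = np.maximum(pred, 0.0)
    return float(out) if out.ndim == 0 else out


def dry_mass(dbh, params: AllometryParams = DEFAULT_ALLOMETRY):
    """Dry biomass (woody kg, foliage kg) of a tree with the given DBH in cm."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh < 0):
        raise ValueError("dbh must be >= 0")
    d2 = dbh**2
    woody = params.woody_a * d2**params.woody_b
    foliage = params.foliage_a * d2**params.foliage_b
    if woody.ndim == 0:
        return float(woody), float(foliage)
    return woody, foliage


def tree_carbon(dbh, params: AllometryParams = DEFAULT_ALLOMETRY):
    """Aboveground carbon stock (kg C) of a tree with the given DBH in cm."""
    woody, foliage = dry_mass(dbh, params)
    carbon = params.carbon_fraction * (np.asarray(woody) + np.asarray(foliage))
    return float(carbon) if carbon.ndim == 0 else carbon
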