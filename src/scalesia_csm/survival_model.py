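"""Repeated-measures logistic survival model with plant and site random intercepts.

Each quarterly monitoring record is one Bernoulli trial: alive (1) or dead (0).
The linear predictor is additive in treatment (six arms, reference level
Cocoon — the arm that carries contrast 0) and plant age in years, with random
intercepts for plant (repeated measures) and site (spatial dependence); plants
are nested within sites.  The marginal likelihood integrates the random
intercepts out by a Laplace approximation (default) or by nested adaptive
Gauss-Hermite quadrature, exploiting the nesting: conditional on a site
intercept the plants factorise, so the joint mode/Hessian have an arrow
structure per site that is solved in closed form.

Fixed-effect significance uses Wald chi-square tests on coefficient blocks.
Population-level survival predictions set the random effects to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "TREATMENTS",
    "DEFAULT_CONTRASTS",
    "SurvivalFixedEffects",
    "SurvivalRandomEffects",
    "SurvivalFit",
    "WaldResult",
    "fit_survival_glmm",
    "glmm_loglik",
    "wald_test",
    "predict_survival",
    "survival_curve",
    "cutoff_summary",
    "time_grid",
]

#: The six restoration arms of the study.
TREATMENTS = (
    "Cocoon",
    "Cocoon+Hydrogel",
    "Control",
    "Hydrogel",
    "Waterboxx",
    "Waterboxx+Hydrogel",
)

#: Fixed-effect treatment contrasts (logit units) relative to Cocoon.
DEFAULT_CONTRASTS: Mapping[str, float] = {
    "Cocoon": 0.0,
    "Cocoon+Hydrogel": 1.973,
    "Control": -0.223,
    "Hydrogel": -0.333,
    "Waterboxx": 0.264,
    "Waterboxx+Hydrogel": 0.711,
}


def _default_contrasts() -> dict[str, float]:
    return dict(DEFAULT_CONTRASTS)


@dataclass(frozen=True)
class SurvivalFixedEffects:
    """Fixed effects of the survival model, in logit units.

    ``intercept`` is the log-odds of being alive at age 0 for the reference
    arm (Cocoon); ``treatment_contrasts`` shift it per arm; ``age_slope`` is
    the change in log-odds per year of age.
    """

    intercept: float = 3.932
    treatment_contrasts: Mapping[str, float] = field(default_factory=_default_contrasts)
    age_slope: float = -0.234

    def __post_init__(self) -> None:
        vals = [self.intercept, self.age_slope, *self.treatment_contrasts.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all fixed effects must be finite")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(sorted(self.treatment_contrasts))

    def linear_predictor(self, treatment: str, age) -> np.ndarray:
        if treatment not in self.treatment_contrasts:
            raise ValueError(
                f"unknown treatment {treatment!r}; valid levels: {list(self.levels)}"
            )
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        return self.intercept + self.treatment_contrasts[treatment] + self.age_slope * age


@dataclass(frozen=True)
class SurvivalRandomEffects:
    """Random-intercept variances (logit^2) for plant and site."""

    var_plant: float = 0.812
    var_site: float = 0.994

    def __post_init__(self) -> None:
        if self.var_plant < 0 or self.var_site < 0:
            raise ValueError("random-effect variances must be >= 0")


@dataclass
class SurvivalFit:
    """Result of fitting the survival GLMM."""

    fixed: SurvivalFixedEffects
    random: SurvivalRandomEffects
    vcov: np.ndarray
    term_names: list[str]
    loglik: float
    n_obs: int
    n_plants: int
    n_sites: int
    converged: bool
    method: str = "laplace"

    def __post_init__(self) -> None:
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (len(self.term_names), len(self.term_names)):
            raise ValueError("vcov dimensions must match the number of fixed effects")

    @property
    def estimates(self) -> np.ndarray:
        beta = [self.fixed.intercept]
        for name in self.term_names[1:-1]:
            beta.append(self.fixed.treatment_contrasts[name])
        beta.append(self.fixed.age_slope)
        return np.asarray(beta)

    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))


@dataclass(frozen=True)
class WaldResult:
    term: str
    chisq: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chisq < 0:
            raise ValueError("chisq must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")


# ---------------------------------------------------------------------------
# design and likelihood machinery
# ---------------------------------------------------------------------------


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .synthetic_cohort import records_to_frame

    return records_to_frame(records)


class _GlmmDesign:
    """Design matrices and index arrays for the nested random-intercept GLMM."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        for col in ("treatment", "age", "alive", "plant_id", "site_id"):
            if col not in frame.columns:
                raise ValueError(f"records lack required column {col!r}")
        if frame["age"].isna().any() or frame["alive"].isna().any():
            raise ValueError("every record needs an age and an alive status")
        self.y = frame["alive"].to_numpy(dtype=float)
        if self.y.min() == self.y.max():
            state = "alive" if self.y.min() == 1 else "dead"
            raise ValueError(
                f"separation: the response is all-{state}; the logistic likelihood "
                "has no interior maximum"
            )
        levels = sorted(frame["treatment"].unique())
        if len(levels) < 2:
            raise ValueError(
                "degenerate design: need at least 2 treatment levels, got "
                f"{levels}"
            )
        self.reference = "Cocoon" if "Cocoon" in levels else levels[0]
        contrast_levels = [t for t in levels if t != self.reference]
        n = len(frame)
        X = np.ones((n, 2 + len(contrast_levels)))
        treat = frame["treatment"].to_numpy()
        for j, lvl in enumerate(contrast_levels):
            X[:, 1 + j] = (treat == lvl).astype(float)
        X[:, -1] = frame["age"].to_numpy(float)
        self.X = X
        self.term_names = ["Intercept", *contrast_levels, "age"]

        plant_codes, plant_ids = pd.factorize(frame["plant_id"])
        site_codes, site_ids = pd.factorize(frame["site_id"])
        self.plant_idx = plant_codes
        self.site_idx = site_codes
        self.n_plants = len(plant_ids)
        self.n_sites = len(site_ids)
        nest = pd.DataFrame({"p": plant_codes, "s": site_codes})
        if nest.groupby("p")["s"].nunique().max() > 1:
            raise ValueError("plants must be nested within sites")
        plant_site = np.full(self.n_plants, -1, dtype=int)
        plant_site[plant_codes] = site_codes
        self.plant_site = plant_site

    # -- penalized log-likelihood of (b, u) given fixed effects ---------------

    def _bern_ll(self, eta: np.ndarray) -> float:
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def _penalized(self, eta, b, u, vp, vs) -> float:
        val = self._bern_ll(eta)
        if vp > 0:
            val -= 0.5 * float(np.sum(b**2)) / vp
        if vs > 0:
            val -= 0.5 * float(np.sum(u**2)) / vs
        return val

    def _mode(self, beta, vp, vs, b, u, tol=1e-10, max_iter=100):
        """Joint mode of the random effects; Newton with arrow-solve per site.

        Returns (b, u, d, schur) where d is the plant-block diagonal of the
        negative Hessian and schur the per-site Schur complement; the joint
        determinant is prod(d) * prod(schur).
        """
        has_p = vp > 0
        has_s = vs > 0
        bc = np.bincount
        pi, si, ps = self.plant_idx, self.site_idx, self.plant_site
        np_, ns = self.n_plants, self.n_sites
        eta_fix = self.X @ beta
        if not has_p:
            b = np.zeros(np_)
        if not has_s:
            u = np.zeros(ns)
        d = np.ones(np_)
        schur = np.ones(ns)
        for _ in range(max_iter):
            eta = eta_fix + b[pi] + u[si]
            mu = expit(eta)
            r = self.y - mu
            w = mu * (1.0 - mu) + 1e-12
            if has_p:
                g_b = bc(pi, weights=r, minlength=np_) - b / vp
                c = bc(pi, weights=w, minlength=np_)
                d = c + 1.0 / vp
            else:
                g_b = np.zeros(np_)
                c = np.zeros(np_)
                d = np.ones(np_)
            if has_s:
                g_u = bc(si, weights=r, minlength=ns) - u / vs
                a = bc(si, weights=w, minlength=ns) + 1.0 / vs
            else:
                g_u = np.zeros(ns)
                a = np.ones(ns)
            gmax = max(
                np.abs(g_b).max() if has_p else 0.0,
                np.abs(g_u).max() if has_s else 0.0,
            )
            cd = c / d
            schur = a - bc(ps, weights=c * cd, minlength=ns) if has_s else np.ones(ns)
            if gmax < tol:
                break
            if has_s:
                du = (g_u - bc(ps, weights=cd * g_b, minlength=ns)) / schur
            else:
                du = np.zeros(ns)
            db = (g_b - c * du[ps]) / d if has_p else np.zeros(np_)
            # backtracking on the penalized objective
            f0 = self._penalized(eta, b, u, vp, vs)
            ftol = 1e-9 * (1.0 + abs(f0))
            step = 1.0
            for _ in range(30):
                b1 = b + step * db
                u1 = u + step * du
                eta1 = eta_fix + b1[pi] + u1[si]
                if self._penalized(eta1, b1, u1, vp, vs) > f0 - ftol:
                    break
                step *= 0.5
            b, u = b1, u1
        return b, u, d, schur

    def loglik_laplace(self, beta, vp, vs, b=None, u=None):
        """Laplace-approximate marginal log-likelihood; returns (ll, b, u)."""
        if b is None:
            b = np.zeros(self.n_plants)
        if u is None:
            u = np.zeros(self.n_sites)
        b, u, d, schur = self._mode(beta, vp, vs, b.copy(), u.copy())
        eta = self.X @ beta + b[self.plant_idx] + u[self.site_idx]
        ll = self._penalized(eta, b, u, vp, vs)
        if vp > 0:
            ll -= 0.5 * (self.n_plants * np.log(vp) + float(np.sum(np.log(d))))
        if vs > 0:
            ll -= 0.5 * (self.n_sites * np.log(vs) + float(np.sum(np.log(schur))))
        return ll, b, u

    # -- profiled Laplace: joint Newton over (beta, b, u) given variances ----

    def _joint_mode(self, vp, vs, beta, b, u, tol=1e-9, max_iter=100):
        """Joint penalized mode over fixed effects and random effects.

        Newton steps solve the full blocked system by eliminating the random
        effects (arrow structure per site) against the dense fixed-effect
        block via a Schur complement.  Returns the mode, the random-effect
        block factors (d, schur) and the fixed-effect Schur complement S,
        whose inverse is the conditional covariance of the fixed effects.
        """
        has_p = vp > 0
        has_s = vs > 0
        bc = np.bincount
        pi, si, ps = self.plant_idx, self.site_idx, self.plant_site
        np_, ns = self.n_plants, self.n_sites
        X, y = self.X, self.y
        p = X.shape[1]
        if not has_p:
            b = np.zeros(np_)
        if not has_s:
            u = np.zeros(ns)
        d = np.ones(np_)
        schur = np.ones(ns)
        S = X.T @ X
        converged = False
        for _ in range(max_iter):
            eta = X @ beta + b[pi] + u[si]
            mu = expit(eta)
            r = y - mu
            w = mu * (1.0 - mu) + 1e-12
            g_beta = X.T @ r
            g_b = bc(pi, weights=r, minlength=np_) - b / vp if has_p else np.zeros(np_)
            g_u = bc(si, weights=r, minlength=ns) - u / vs if has_s else np.zeros(ns)
            c = bc(pi, weights=w, minlength=np_) if has_p else np.zeros(np_)
            d = c + 1.0 / vp if has_p else np.ones(np_)
            a = bc(si, weights=w, minlength=ns) + 1.0 / vs if has_s else np.ones(ns)
            cd = c / d
            schur = a - bc(ps, weights=c * cd, minlength=ns) if has_s else np.ones(ns)

            WX = X * w[:, None]
            su = (
                np.stack([bc(si, weights=WX[:, k], minlength=ns) for k in range(p)], axis=1)
                if has_s
                else np.zeros((ns, p))
            )
            sp = (
                np.stack([bc(pi, weights=WX[:, k], minlength=np_) for k in range(p)], axis=1)
                if has_p
                else np.zeros((np_, p))
            )

            def arrow_solve(yu, yb):
                du = (yu - bc(ps, weights=cd * yb, minlength=ns)) / schur if has_s else np.zeros_like(yu)
                db = (yb - c * du[ps]) / d if has_p else np.zeros_like(yb)
                return du, db

            AU_u = np.empty((ns, p))
            AU_b = np.empty((np_, p))
            for k in range(p):
                AU_u[:, k], AU_b[:, k] = arrow_solve(su[:, k], sp[:, k])
            S = X.T @ WX - (su.T @ AU_u + sp.T @ AU_b)

            gmax = max(
                np.abs(g_beta).max(),
                np.abs(g_b).max() if has_p else 0.0,
                np.abs(g_u).max() if has_s else 0.0,
            )
            if gmax < tol:
                converged = True
                break
            du0, db0 = arrow_solve(g_u, g_b)
            dbeta = np.linalg.solve(S, g_beta - (su.T @ du0 + sp.T @ db0))
            du = du0 - AU_u @ dbeta
            db = db0 - AU_b @ dbeta
            f0 = self._penalized(eta, b, u, vp, vs)
            ftol = 1e-9 * (1.0 + abs(f0))
            step = 1.0
            for _ in range(30):
                beta1 = beta + step * dbeta
                b1 = b + step * db
                u1 = u + step * du
                eta1 = X @ beta1 + b1[pi] + u1[si]
                if self._penalized(eta1, b1, u1, vp, vs) > f0 - ftol:
                    break
                step *= 0.5
            beta, b, u = beta1, b1, u1
        return beta, b, u, d, schur, S, converged

    def fixed_information(self, beta, vp, vs, b=None, u=None):
        """Conditional Fisher information of the fixed effects.

        X'WX corrected for random-effect uncertainty (the Schur complement of
        the random-effect block), evaluated at the random-effect mode for the
        given parameters.  Its inverse is the reported vcov.
        """
        bc = np.bincount
        pi, si, ps = self.plant_idx, self.site_idx, self.plant_site
        np_, ns = self.n_plants, self.n_sites
        p = self.X.shape[1]
        has_p = vp > 0
        has_s = vs > 0
        if b is None:
            b = np.zeros(np_)
        if u is None:
            u = np.zeros(ns)
        b, u, d, schur = self._mode(beta, vp, vs, b.copy(), u.copy())
        eta = self.X @ beta + b[pi] + u[si]
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        c = bc(pi, weights=w, minlength=np_) if has_p else np.zeros(np_)
        cd = c / d
        WX = self.X * w[:, None]
        su = (
            np.stack([bc(si, weights=WX[:, k], minlength=ns) for k in range(p)], axis=1)
            if has_s
            else np.zeros((ns, p))
        )
        sp = (
            np.stack([bc(pi, weights=WX[:, k], minlength=np_) for k in range(p)], axis=1)
            if has_p
            else np.zeros((np_, p))
        )
        AU_u = np.empty((ns, p))
        AU_b = np.empty((np_, p))
        for k in range(p):
            yu, yb = su[:, k], sp[:, k]
            du = (yu - bc(ps, weights=cd * yb, minlength=ns)) / schur if has_s else np.zeros(ns)
            db = (yb - c * du[ps]) / d if has_p else np.zeros(np_)
            AU_u[:, k], AU_b[:, k] = du, db
        return self.X.T @ WX - (su.T @ AU_u + sp.T @ AU_b)

    def profile_loglik(self, vp, vs, beta, b, u):
        """Laplace log-likelihood with the fixed effects profiled at the joint mode."""
        beta, b, u, d, schur, S, ok = self._joint_mode(vp, vs, beta, b, u)
        eta = self.X @ beta + b[self.plant_idx] + u[self.site_idx]
        ll = self._penalized(eta, b, u, vp, vs)
        if vp > 0:
            ll -= 0.5 * (self.n_plants * np.log(vp) + float(np.sum(np.log(d))))
        if vs > 0:
            ll -= 0.5 * (self.n_sites * np.log(vs) + float(np.sum(np.log(schur))))
        return ll, beta, b, u, S, ok

    def loglik_agq(self, beta, vp, vs, k=15):
        """Nested adaptive Gauss-Hermite marginal log-likelihood.

        Outer quadrature over the site intercept (centred on the joint Laplace
        mode with the Schur-complement curvature), inner adaptive quadrature
        over each plant intercept conditional on the outer node.  Intended for
        small instances; cost grows with k^2 passes over the data.
        """
        if vp <= 0 and vs <= 0:
            return self._bern_ll(self.X @ beta)
        b0, u0, d0, schur = self._mode(
            beta, vp, vs, np.zeros(self.n_plants), np.zeros(self.n_sites)
        )
        x, wq = np.polynomial.hermite.hermgauss(k)
        logw = np.log(wq)
        pi, si, ps = self.plant_idx, self.site_idx, self.plant_site
        eta_fix = self.X @ beta

        if vs <= 0:
            # single layer: adaptive GH per plant only
            site_log = self._plant_logints(eta_fix, np.zeros(self.n_sites), b0, vp, x, logw, k)
            return float(np.sum(site_log))

        site_contrib = np.empty((self.n_sites, k))
        half_log_outer = 0.5 * np.log(2.0 / schur)
        for j in range(k):
            u_j = u0 + np.sqrt(2.0 / schur) * x[j]
            if vp > 0:
                plant_sum = self._plant_logints(eta_fix, u_j, b0, vp, x, logw, k)
            else:
                eta = eta_fix + u_j[si]
                ll_obs = self.y * eta - np.logaddexp(0.0, eta)
                plant_sum = np.bincount(si, weights=ll_obs, minlength=self.n_sites)
            log_phi_u = -0.5 * np.log(2.0 * np.pi * vs) - 0.5 * u_j**2 / vs
            site_contrib[:, j] = logw[j] + x[j] ** 2 + plant_sum + log_phi_u
        return float(np.sum(logsumexp(site_contrib, axis=1) + half_log_outer))

    def _plant_logints(self, eta_fix, u_site, b_start, vp, x, logw, k):
        """log of per-plant integrals over the plant intercept, summed per site.

        Returns an array over sites: sum_{plants in s} log I_p given the site
        intercepts ``u_site``.
        """
        bc = np.bincount
        pi, si, ps = self.plant_idx, self.site_idx, self.plant_site
        np_ = self.n_plants
        offs = eta_fix + u_site[si]
        b = b_start.copy()
        for _ in range(60):
            eta = offs + b[pi]
            mu = expit(eta)
            g = bc(pi, weights=self.y - mu, minlength=np_) - b / vp
            h = bc(pi, weights=mu * (1 - mu), minlength=np_) + 1.0 / vp
            step = g / h
            b = b + step
            if np.abs(g).max() < 1e-10:
                break
        eta = offs + b[pi]
        mu = expit(eta)
        h = bc(pi, weights=mu * (1 - mu), minlength=np_) + 1.0 / vp
        scale = np.sqrt(2.0 / h)
        contrib = np.empty((np_, k))
        for i in range(k):
            b_i = b + scale * x[i]
            eta_i = offs + b_i[pi]
            ll_obs = self.y * eta_i - np.logaddexp(0.0, eta_i)
            ll_p = bc(pi, weights=ll_obs, minlength=np_)
            log_phi = -0.5 * np.log(2.0 * np.pi * vp) - 0.5 * b_i**2 / vp
            contrib[:, i] = logw[i] + x[i] ** 2 + ll_p + log_phi
        log_int = logsumexp(contrib, axis=1) + np.log(scale)
        return bc(ps, weights=log_int, minlength=self.n_sites)


def glmm_loglik(
    records,
    fixed: SurvivalFixedEffects,
    random: SurvivalRandomEffects,
    method: str = "laplace",
    quad_nodes: int = 15,
) -> float:
    """Marginal log-likelihood of the data at the given parameter values.

    ``method`` is ``"laplace"`` or ``"agq"`` (nested adaptive Gauss-Hermite
    with ``quad_nodes`` nodes per layer).  Useful as an independent check of
    the fitting objective.
    """
    design = _GlmmDesign(_as_frame(records))
    beta = _beta_from_fixed(fixed, design.term_names, design.reference)
    if method == "laplace":
        ll, _, _ = design.loglik_laplace(beta, random.var_plant, random.var_site)
        return float(ll)
    if method == "agq":
        return float(
            design.loglik_agq(beta, random.var_plant, random.var_site, k=quad_nodes)
        )
    raise ValueError("method must be 'laplace' or 'agq'")


def _beta_from_fixed(fixed: SurvivalFixedEffects, term_names, reference) -> np.ndarray:
    beta = [fixed.intercept]
    for name in term_names[1:-1]:
        beta.append(fixed.treatment_contrasts[name])
    beta.append(fixed.age_slope)
    return np.asarray(beta, dtype=float)


_LOGVAR_BOUNDS = (-12.0, 6.0)


def fit_survival_glmm(
    records,
    approx: str = "laplace",
    quad_nodes: int = 7,
    fixed_variances: tuple[float, float] | None = None,
) -> SurvivalFit:
    """Fit the logistic survival GLMM by maximum marginal likelihood.

    Parameters
    ----------
    records:
        Monitoring table (DataFrame) or list of MonitoringRecord.
    approx:
        ``"laplace"`` (default) or ``"agq"`` — the random-effect integral
        approximation used as the fitting objective.  ``agq`` is intended for
        small instances.
    quad_nodes:
        Nodes per quadrature layer when ``approx="agq"``.
    fixed_variances:
        Optionally pin (var_plant, var_site) instead of estimating them;
        ``(0.0, 0.0)`` reduces the model to a plain logistic regression.

    Returns ``converged=False`` (rather than raising) when the optimizer
    stalls.  Variance estimates are reported on the natural scale, floored
    at 0.
    """
    frame = _as_frame(records)
    design = _GlmmDesign(frame)
    if design.n_sites < 2:
        raise ValueError("need at least 2 sites to estimate a site random effect")
    if approx not in ("laplace", "agq"):
        raise ValueError("approx must be 'laplace' or 'agq'")

    # starting values: fixed effects from the no-random-effect logistic fit
    glm = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
    beta0 = np.asarray(glm.params, dtype=float)
    p = len(beta0)

    # warm-started profile state (fixed effects and modes carried across evals)
    state = {
        "beta": beta0.copy(),
        "b": np.zeros(design.n_plants),
        "u": np.zeros(design.n_sites),
        "S": None,
        "inner_ok": True,
    }

    def profile_nll(logvars):
        vp = float(np.exp(logvars[0])) if logvars[0] > _LOGVAR_BOUNDS[0] + 1e-9 else 0.0
        vs = float(np.exp(logvars[1])) if logvars[1] > _LOGVAR_BOUNDS[0] + 1e-9 else 0.0
        ll, beta, b, u, S, ok = design.profile_loglik(vp, vs, state["beta"], state["b"], state["u"])
        state.update(beta=beta, b=b, u=u, S=S, inner_ok=ok)
        return -ll

    if fixed_variances is not None:
        vp_hat, vs_hat = fixed_variances
        if vp_hat < 0 or vs_hat < 0:
            raise ValueError("fixed variances must be >= 0")
        _, beta_start, b0, u0, S, inner_ok = design.profile_loglik(
            vp_hat, vs_hat, state["beta"], state["b"], state["u"]
        )
        if vp_hat == 0 and vs_hat == 0:
            # no random effects: the joint mode IS the ML logistic fit
            beta_hat = beta_start
            loglik = design._bern_ll(design.X @ beta_hat)
            converged = inner_ok
        else:
            mode = {"b": b0, "u": u0}

            def neg_beta(bb):
                ll, b, u = design.loglik_laplace(bb, vp_hat, vs_hat, mode["b"], mode["u"])
                mode["b"], mode["u"] = b, u
                return -ll

            opt = minimize(neg_beta, beta_start, method="L-BFGS-B")
            beta_hat = opt.x
            loglik = -float(opt.fun)
            converged = bool(opt.success) and inner_ok
            S = design.fixed_information(beta_hat, vp_hat, vs_hat, mode["b"], mode["u"])
    elif approx == "laplace":
        # stage 1: cheap profiled fit (fixed effects at the joint penalized
        # mode) to locate the variance region and warm the mode caches
        pre = minimize(
            profile_nll,
            np.array([0.0, 0.0]),
            method="L-BFGS-B",
            bounds=[_LOGVAR_BOUNDS, _LOGVAR_BOUNDS],
        )
        profile_nll(pre.x)
        # stage 2: optimize the Laplace criterion over all parameters; the
        # joint-mode profile attenuates the fixed effects, the full
        # optimization does not
        mode = {"b": state["b"].copy(), "u": state["u"].copy()}

        def neg(theta):
            vp = float(np.exp(theta[p])) if theta[p] > _LOGVAR_BOUNDS[0] + 1e-9 else 0.0
            vs = (
                float(np.exp(theta[p + 1]))
                if theta[p + 1] > _LOGVAR_BOUNDS[0] + 1e-9
                else 0.0
            )
            ll, b, u = design.loglik_laplace(theta[:p], vp, vs, mode["b"], mode["u"])
            mode["b"], mode["u"] = b, u
            return -ll

        theta0 = np.concatenate([state["beta"], pre.x])
        bounds = [(None, None)] * p + [_LOGVAR_BOUNDS, _LOGVAR_BOUNDS]
        opt = minimize(neg, theta0, method="L-BFGS-B", bounds=bounds)
        beta_hat = opt.x[:p]
        vp_hat = float(np.exp(opt.x[p])) if opt.x[p] > _LOGVAR_BOUNDS[0] + 1e-8 else 0.0
        vs_hat = (
            float(np.exp(opt.x[p + 1]))
            if opt.x[p + 1] > _LOGVAR_BOUNDS[0] + 1e-8
            else 0.0
        )
        loglik = -float(opt.fun)
        converged = bool(opt.success) and state["inner_ok"]
        S = design.fixed_information(beta_hat, vp_hat, vs_hat, mode["b"], mode["u"])
    else:
        # adaptive quadrature objective: full-parameter optimization, intended
        # for small instances; start from the profiled Laplace solution
        lap = fit_survival_glmm(frame, approx="laplace")
        beta_start = _beta_from_fixed(lap.fixed, design.term_names, design.reference)
        theta0 = np.concatenate(
            [
                beta_start,
                [
                    np.log(max(lap.random.var_plant, 1e-5)),
                    np.log(max(lap.random.var_site, 1e-5)),
                ],
            ]
        )

        def neg(theta):
            return -design.loglik_agq(
                theta[:p], np.exp(theta[p]), np.exp(theta[p + 1]), k=quad_nodes
            )

        bounds = [(None, None)] * p + [_LOGVAR_BOUNDS, _LOGVAR_BOUNDS]
        opt = minimize(neg, theta0, method="L-BFGS-B", bounds=bounds)
        beta_hat = opt.x[:p]
        vp_hat = float(np.exp(opt.x[p]))
        vs_hat = float(np.exp(opt.x[p + 1]))
        loglik = -float(opt.fun)
        converged = bool(opt.success)
        S = design.fixed_information(beta_hat, vp_hat, vs_hat)

    if not converged:
        logger.warning("survival GLMM fit did not fully converge")

    vcov, pd_ok = _safe_inverse(S)
    converged = converged and pd_ok

    contrasts = {design.reference: 0.0}
    for j, name in enumerate(design.term_names[1:-1], start=1):
        contrasts[name] = float(beta_hat[j])
    fixed = SurvivalFixedEffects(
        intercept=float(beta_hat[0]),
        treatment_contrasts=contrasts,
        age_slope=float(beta_hat[-1]),
    )
    random = SurvivalRandomEffects(var_plant=max(vp_hat, 0.0), var_site=max(vs_hat, 0.0))
    return SurvivalFit(
        fixed=fixed,
        random=random,
        vcov=vcov,
        term_names=design.term_names,
        loglik=loglik,
        n_obs=len(design.y),
        n_plants=design.n_plants,
        n_sites=design.n_sites,
        converged=converged,
        method=approx,
    )


def _safe_inverse(A):
    """Inverse of a nominally positive-definite matrix; (pinv, False) fallback."""
    try:
        L = np.linalg.cholesky(A)
        inv = np.linalg.inv(A)
        inv = 0.5 * (inv + inv.T)
        return inv, True
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(A)
        return 0.5 * (inv + inv.T), False


# ---------------------------------------------------------------------------
# Wald tests and prediction
# ---------------------------------------------------------------------------

_TERM_ALIASES = {"treatment": "Treatment", "age": "Age", "intercept": "Intercept"}


def wald_test(fit: SurvivalFit, term: str) -> WaldResult:
    """Wald chi-square test of a fixed-effect block.

    ``term`` is "Treatment" (the 5 contrast coefficients jointly), "Age" or
    "Intercept".  The statistic is c' V^{-1} c over the term's coefficient
    block of the fitted covariance.
    """
    term = _TERM_ALIASES.get(term.lower(), term)
    names = fit.term_names
    if term == "Treatment":
        idx = [i for i, n in enumerate(names) if n not in ("Intercept", "age")]
    elif term == "Age":
        idx = [names.index("age")]
    elif term == "Intercept":
        idx = [names.index("Intercept")]
    else:
        raise ValueError("term must be one of 'Treatment', 'Age', 'Intercept'")
    if not idx:
        raise ValueError(f"no coefficients found for term {term!r}")
    c = fit.estimates[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    try:
        sol = np.linalg.solve(V, c)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular covariance block for term {term!r}") from err
    if not np.all(np.isfinite(sol)):
        raise ValueError(f"singular covariance block for term {term!r}")
    chisq = float(max(c @ sol, 0.0))
    df = len(idx)
    return WaldResult(term=term, chisq=chisq, df=df, p=float(chi2.sf(chisq, df)))


def predict_survival(fixed: SurvivalFixedEffects, treatment: str, age):
    """Population-level survival probability (random effects at zero)."""
    out = expit(fixed.linear_predictor(treatment, age))
    return float(out) if np.ndim(out) == 0 else out


def time_grid(horizon: float, step: float) -> np.ndarray:
    """Regular age grid from 0 to horizon inclusive.

    When step does not divide the horizon (or exceeds it) the horizon itself
    is appended, so the final entry is always the horizon.
    """
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be > 0")
    if step >= horizon:
        return np.array([0.0, float(horizon)])
    n = int(np.floor(horizon / step + 1e-9))
    t = np.arange(n + 1) * step
    if t[-1] < horizon - 1e-9:
        t = np.append(t, horizon)
    else:
        t[-1] = horizon
    return t


def survival_curve(
    fixed: SurvivalFixedEffects, treatment: str, horizon: float, step: float
) -> pd.DataFrame:
    """Dense survival curve: DataFrame with columns age, survival."""
    ages = time_grid(horizon, step)
    return pd.DataFrame({"age": ages, "survival": predict_survival(fixed, treatment, ages)})


def cutoff_summary(
    fixed: SurvivalFixedEffects, cutoffs: Sequence[float] = (1.0, 4.0)
) -> pd.DataFrame:
    """Predicted survival per treatment at the reporting cut-off ages.

    The study reports two cut-offs: 1 year (seedling establishment) and
    4 years (onset of maturity).
    """
    rows = []
    for treatment in sorted(fixed.treatment_contrasts):
        row = {"treatment": treatment}
        for c in cutoffs:
            row[f"survival_{c:g}y"] = predict_survival(fixed, treatment, c)
        rows.append(row)
    return pd.DataFrame(rows)
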