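"""End-to-end pipeline: simulate -> fit survival -> fit DBH -> project -> offset.

Binds the five modelling stages into one reproducible run driven by a single
YAML configuration and one master seed.  Every intermediate table is written
as plain CSV, the two headline figures (survival curves and the carbon
trajectory) as PNG, and a JSON manifest records the seeds, configuration and
SHA-256 hashes of the tables so any stage can be re-run and checked in
isolation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon_accounting import CO2_PER_C, OffsetInputs, footprint_reduction, total_storage
from .growth_allometry import (
    DEFAULT_ALLOMETRY,
    AllometryParams,
    DbhModelFit,
    extract_dbh_subsample,
    fit_dbh_model,
)
from .stand_projection import (
    ALL_DATA,
    ProjectionConfig,
    compare_treatments,
    per_tree_trajectory,
    project_stand,
)
from .survival_model import (
    SurvivalFit,
    SurvivalFixedEffects,
    SurvivalRandomEffects,
    cutoff_summary,
    fit_survival_glmm,
    survival_curve,
    wald_test,
)
from .synthetic_cohort import (
    CohortConfig,
    GrowthParams,
    generate_cohort_frame,
    read_monitoring_csv,
    write_monitoring_csv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "write_survival_fit_csv",
    "read_survival_fit_csv",
    "write_dbh_fit_csv",
    "read_dbh_fit_csv",
    "survival_summary_text",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    growth: GrowthParams = field(default_factory=GrowthParams)
    survival_fixed: SurvivalFixedEffects = field(default_factory=SurvivalFixedEffects)
    survival_random: SurvivalRandomEffects = field(default_factory=SurvivalRandomEffects)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    offset_area: float = 723.0
    offset_annual_footprint: float = 523_000.0
    offset_co2_per_c: float = CO2_PER_C
    seed: int = 0
    outdir: Path = Path("csm-output")


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "growth": GrowthParams,
    "survival_fixed": SurvivalFixedEffects,
    "survival_random": SurvivalRandomEffects,
    "projection": ProjectionConfig,
    "allometry": AllometryParams,
}
_SCALAR_KEYS = {
    "offset_area",
    "offset_annual_footprint",
    "offset_co2_per_c",
    "seed",
    "outdir",
}
_DATE_FIELDS = {"planting_window", "census_end", "dbh_measure_cutoff"}


def _coerce_dates(cls, kwargs: dict[str, Any]) -> dict[str, Any]:
    def to_date(v):
        if isinstance(v, dt.date):
            return v
        return dt.date.fromisoformat(str(v))

    for key in list(kwargs):
        if key == "planting_window":
            kwargs[key] = tuple(to_date(v) for v in kwargs[key])
        elif key in _DATE_FIELDS:
            kwargs[key] = to_date(kwargs[key])
    return kwargs


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict, rejecting unknown keys."""
    unknown = set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            payload = dict(data[section])
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(payload) - valid
            if bad:
                raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
            kwargs[section] = cls(**_coerce_dates(cls, payload))
    for key in _SCALAR_KEYS & set(data):
        kwargs[key] = Path(data[key]) if key == "outdir" else data[key]
    return PipelineConfig(**kwargs)


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# fit report readers/writers
# ---------------------------------------------------------------------------


def write_survival_fit_csv(fit: SurvivalFit, path) -> None:
    ses = fit.std_errors()
    est = fit.estimates
    rows = []
    for name, e, se in zip(fit.term_names, est, ses):
        z = e / se if se > 0 else np.nan
        rows.append(
            {"kind": "fixed", "term": name, "estimate": e, "std_error": se, "z": z}
        )
    rows.append(
        {
            "kind": "random",
            "term": "Plant_ID",
            "estimate": fit.random.var_plant,
            "std_error": np.nan,
            "z": np.nan,
        }
    )
    rows.append(
        {
            "kind": "random",
            "term": "Site",
            "estimate": fit.random.var_site,
            "std_error": np.nan,
            "z": np.nan,
        }
    )
    for key, value in (
        ("loglik", fit.loglik),
        ("n_obs", fit.n_obs),
        ("n_plants", fit.n_plants),
        ("n_sites", fit.n_sites),
        ("converged", int(fit.converged)),
    ):
        rows.append(
            {"kind": "meta", "term": key, "estimate": value, "std_error": np.nan, "z": np.nan}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_fit_csv(path) -> tuple[SurvivalFixedEffects, SurvivalRandomEffects]:
    table = pd.read_csv(path)
    fixed_rows = table[table["kind"] == "fixed"].set_index("term")["estimate"]
    contrast_terms = [t for t in fixed_rows.index if t not in ("Intercept", "age")]
    contrasts = {"Cocoon": 0.0}
    contrasts.update({t: float(fixed_rows[t]) for t in contrast_terms})
    fixed = SurvivalFixedEffects(
        intercept=float(fixed_rows["Intercept"]),
        treatment_contrasts=contrasts,
        age_slope=float(fixed_rows["age"]),
    )
    random_rows = table[table["kind"] == "random"].set_index("term")["estimate"]
    random = SurvivalRandomEffects(
        var_plant=float(random_rows["Plant_ID"]), var_site=float(random_rows["Site"])
    )
    return fixed, random


def write_dbh_fit_csv(fit: DbhModelFit, path) -> None:
    pd.DataFrame([dataclasses.asdict(fit)]).to_csv(path, index=False)


def read_dbh_fit_csv(path) -> DbhModelFit:
    row = pd.read_csv(path).iloc[0].to_dict()
    return DbhModelFit(**{k: (int(v) if k == "n_obs" else float(v)) for k, v in row.items()})


def survival_summary_text(fit: SurvivalFit) -> str:
    """Human-readable fit summary: Wald tests, random effects, fixed effects."""
    lines = ["Survival model (logistic GLMM, plant and site random intercepts)", ""]
    lines.append("Wald Chisq Test")
    lines.append(f"{'Term':<22}{'Chisq':>10}{'DF':>4}{'p':>10}")
    for term in ("Intercept", "Treatment", "Age"):
        try:
            w = wald_test(fit, term)
            lines.append(f"{term:<22}{w.chisq:>10.3f}{w.df:>4d}{w.p:>10.4g}")
        except ValueError:
            lines.append(f"{term:<22}{'--':>10}{'--':>4}{'--':>10}")
    lines.append("")
    lines.append("Random effects")
    lines.append(f"{'Groups':<22}{'Variance':>10}{'Std.Dev':>10}")
    lines.append(
        f"{'Plant_ID':<22}{fit.random.var_plant:>10.3f}{np.sqrt(fit.random.var_plant):>10.3f}"
    )
    lines.append(
        f"{'Site':<22}{fit.random.var_site:>10.3f}{np.sqrt(fit.random.var_site):>10.3f}"
    )
    lines.append("")
    lines.append("Fixed effects")
    lines.append(f"{'Term':<22}{'Estimate':>10}{'Std.E':>10}{'z':>8}")
    for name, e, se in zip(fit.term_names, fit.estimates, fit.std_errors()):
        z = e / se if se > 0 else float("nan")
        lines.append(f"{name:<22}{e:>10.3f}{se:>10.3f}{z:>8.2f}")
    lines.append("")
    lines.append(
        f"log-likelihood {fit.loglik:.2f} on {fit.n_obs} records "
        f"({fit.n_plants} plants, {fit.n_sites} sites); converged={fit.converged}"
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def _plot_survival(fixed: SurvivalFixedEffects, horizon: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for treatment in sorted(fixed.treatment_contrasts):
        curve = survival_curve(fixed, treatment, horizon=horizon, step=0.1)
        ax.plot(curve["age"], curve["survival"], label=treatment)
    for cutoff in (1.0, 4.0):
        if cutoff <= horizon:
            ax.axvline(cutoff, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Predicted survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_projection(results: Mapping[str, Any], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, res in results.items():
        lw = 2.0 if label == ALL_DATA else 1.0
        color = "black" if label == ALL_DATA else None
        (line,) = ax.plot(res.times, res.mean_carbon, label=label, lw=lw, color=color)
        ax.fill_between(
            res.times,
            res.mean_carbon - res.sd_carbon,
            np.maximum(res.mean_carbon + res.sd_carbon, 0.0),
            alpha=0.12,
            color=line.get_color(),
        )
    ax.set_xlabel("Time since planting (years)")
    ax.set_ylabel("Stand carbon (Mg C/ha)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run manifest.

    All randomness flows from ``config.seed``: the cohort uses the seed in its
    own section (overridden by the master seed's first substream) and the
    projection uses the second substream.  Two runs with identical config and
    seed produce identical tables, hence identical manifests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    cohort_cfg = dataclasses.replace(config.cohort, seed=int(sub[0]))
    proj_cfg = dataclasses.replace(config.projection, seed=int(sub[1]))
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {"cohort": int(sub[0]), "projection": int(sub[1])},
        "stages": {},
        "summary": {},
    }

    def record_stage(name: str, outputs: Mapping[str, Path]) -> None:
        manifest["stages"][name] = {
            "outputs": {
                str(p.name): (_sha256(p) if p.suffix in (".csv", ".json", ".txt") else "unhashed")
                for p in outputs.values()
            }
        }
        logger.info("stage %s complete: %s", name, [str(p) for p in outputs.values()])

    # 1. simulate -------------------------------------------------------------
    try:
        frame = generate_cohort_frame(
            cohort_cfg, config.growth, config.survival_fixed, config.survival_random
        )
        monitoring_path = outdir / "monitoring.csv"
        write_monitoring_csv(frame, monitoring_path)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError("simulate", err) from err
    record_stage("simulate", {"monitoring": monitoring_path})
    manifest["summary"]["n_plants"] = int(frame["plant_id"].nunique())
    manifest["summary"]["n_records"] = int(len(frame))

    # 2. fit survival ---------------------------------------------------------
    try:
        fit = fit_survival_glmm(frame)
        fit_path = outdir / "survival_fit.csv"
        write_survival_fit_csv(fit, fit_path)
        summary_path = outdir / "survival_summary.txt"
        summary_path.write_text(survival_summary_text(fit) + "\n")
        _plot_survival(fit.fixed, config.projection.horizon, outdir / "survival_curves.png")
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError("fit-survival", err) from err
    record_stage(
        "fit-survival",
        {"fit": fit_path, "summary": summary_path, "plot": outdir / "survival_curves.png"},
    )
    cutoffs = tuple(c for c in (1.0, 4.0) if c <= config.projection.horizon)
    if cutoffs:
        cut = cutoff_summary(fit.fixed, cutoffs)
        manifest["summary"]["survival_cutoffs"] = {
            row["treatment"]: {
                k: round(float(v), 4) for k, v in row.items() if k != "treatment"
            }
            for row in cut.to_dict("records")
        }

    # 3. fit DBH --------------------------------------------------------------
    try:
        subsample = extract_dbh_subsample(frame)
        dbh_fit = fit_dbh_model(subsample, records=frame)
        dbh_path = outdir / "dbh_fit.csv"
        write_dbh_fit_csv(dbh_fit, dbh_path)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError("fit-dbh", err) from err
    record_stage("fit-dbh", {"fit": dbh_path})
    manifest["summary"]["dbh_model"] = {
        "intercept_cm": round(dbh_fit.intercept, 4),
        "age_coef_cm_per_year": round(dbh_fit.age_coef, 4),
        "height_coef_cm_per_cm": round(dbh_fit.height_coef, 6),
        "r_age": round(dbh_fit.r_age, 4),
        "r_height": round(dbh_fit.r_height, 4),
        "n_subsample": dbh_fit.n_obs,
    }

    # 4. project --------------------------------------------------------------
    try:
        tree_curve = per_tree_trajectory(
            config.growth,
            dbh_fit,
            config.allometry,
            horizon=proj_cfg.horizon,
            step=proj_cfg.step,
            initial_height=config.cohort.init_height_mean,
        )
        allocation = config.cohort.treatment_allocation
        result = project_stand(proj_cfg, fit.fixed, tree_curve, allocation)
        traj_path = outdir / "trajectory.csv"
        result.to_frame().to_csv(traj_path, index=False)
        table = compare_treatments(proj_cfg, fit.fixed, tree_curve, allocation=allocation)
        table_path = outdir / "treatment_comparison.csv"
        table.to_csv(table_path, index=False)
        named = {ALL_DATA: result}
        for treatment in ("Control", "Waterboxx"):
            if treatment in fit.fixed.treatment_contrasts:
                named[treatment] = project_stand(
                    dataclasses.replace(proj_cfg, treatment=treatment),
                    fit.fixed,
                    tree_curve,
                    allocation,
                )
        _plot_projection(named, outdir / "carbon_projection.png")
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError("project", err) from err
    record_stage(
        "project",
        {
            "trajectory": traj_path,
            "treatments": table_path,
            "plot": outdir / "carbon_projection.png",
        },
    )
    year_end = float(result.mean_carbon[-1])
    manifest["summary"]["stand_carbon_mg_c_per_ha"] = round(year_end, 3)
    manifest["summary"]["stand_carbon_se"] = round(float(result.se_carbon[-1]), 4)
    manifest["summary"]["per_tree_carbon_kg_c"] = round(float(tree_curve[-1]), 2)
    manifest["summary"]["horizon_years"] = proj_cfg.horizon

    # 5. offset ---------------------------------------------------------------
    try:
        inputs = OffsetInputs(
            per_ha_carbon=year_end,
            area=config.offset_area,
            annual_footprint=config.offset_annual_footprint,
            horizon=proj_cfg.horizon,
            co2_per_c=config.offset_co2_per_c,
        )
        storage = total_storage(year_end, config.offset_area)
        reduction = footprint_reduction(inputs)
        offset_path = outdir / "offset_report.csv"
        pd.DataFrame(
            [
                {
                    "per_ha_carbon_mg": year_end,
                    "area_ha": config.offset_area,
                    "total_storage_mg_c": storage,
                    "total_storage_mg_co2": storage * config.offset_co2_per_c,
                    "annual_footprint_mg_co2": config.offset_annual_footprint,
                    "horizon_years": proj_cfg.horizon,
                    "footprint_reduction_pct": reduction,
                }
            ]
        ).to_csv(offset_path, index=False)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError("offset", err) from err
    record_stage("offset", {"report": offset_path})
    manifest["summary"]["total_storage_mg_c"] = round(storage, 1)
    manifest["summary"]["footprint_reduction_pct"] = round(reduction, 4)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
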