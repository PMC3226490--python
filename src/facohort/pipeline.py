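"""End-to-end orchestration: synthesize/load → exposure models → assignment →
association models → MCAR diagnostics → Bayesian sensitivity → reports."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import Priors, fit_joint_bayes, mcar_univariate_tests
from .config import SynthConfig
from .errors import ConfigError
from .exposure import (
    annual_means,
    assign_cohort_exposure,
    fit_linear_exposure_model,
    fit_logistic_exposure_model,
    fit_multinomial_tertile_model,
    univariate_screen,
)
from .health import covariate_screen, fit_binary_lri, fit_multinomial_lri
from .io_ import (
    read_dwellings,
    read_measurements,
    read_subjects,
    validate_tables,
    write_tables,
)
from .synth import make_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``inputs`` or ``synth`` is set."""

    outdir: str = "facohort_out"
    inputs: dict | None = None  # {"dwellings": path, "measurements": path, "subjects": path}
    synth: SynthConfig | None = None
    min_seasons: int = 3
    loq_policy: str = "half_loq"
    exposure_screen_alpha: float = 0.20
    exposure_forced_in: tuple = ()
    health_exposure_coding: str = "continuous"
    health_forced_in: tuple = ("ses",)
    health_screen_alpha: float = 0.20
    bayes_enabled: bool = True
    bayes_outcome: str = "binary"
    bayes_n_iter: int = 10000
    bayes_n_burnin: int = 1000
    bayes_priors: Priors = field(default_factory=Priors)
    seed: int = 0

    def __post_init__(self):
        if (self.inputs is None) == (self.synth is None):
            raise ConfigError("exactly one of 'inputs' and 'synth' must be provided")
        if self.inputs is not None:
            missing = {"dwellings", "measurements", "subjects"} - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing paths: {sorted(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synth") is not None and not isinstance(d["synth"], SynthConfig):
            synth = dict(d["synth"])
            if "seed" not in synth:
                if "seed" not in d:
                    raise ConfigError("a seed is mandatory when a synth block is present")
                synth["seed"] = d["seed"]
            d["synth"] = SynthConfig.from_dict(synth)
        if "bayes_priors" in d and not isinstance(d["bayes_priors"], Priors):
            d["bayes_priors"] = Priors(**d["bayes_priors"])
        for key in ("exposure_forced_in", "health_forced_in"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _json_dump(obj, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write every artifact plus ``run_report.json``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)
        report["stages"].append(name)

    # -- inputs ------------------------------------------------------------
    if config.synth is not None:
        stage("synth")
        dwellings, measurements, subjects, _truth = make_cohort(config.synth)
        paths = write_tables(outdir, dwellings, measurements, subjects)
        config.synth.to_json(outdir / "synth_config.json")
        report["inputs"] = paths
    else:
        stage("load")
        dwellings = read_dwellings(config.inputs["dwellings"])
        measurements = read_measurements(config.inputs["measurements"])
        subjects = read_subjects(config.inputs["subjects"])
        report["inputs"] = dict(config.inputs)

    stage("validate")
    vrep = validate_tables(dwellings, measurements, subjects)
    _json_dump(vrep.to_dict(), outdir / "validation_report.json")
    if not vrep.ok:
        raise ConfigError(f"stage 'validate' failed: {vrep.errors[:3]}")
    report["warnings"].extend(vrep.warnings)
    report["n_dwellings"] = int(len(dwellings))
    report["n_subjects"] = int(len(subjects))

    # -- exposure models ---------------------------------------------------
    stage("fit-exposure")
    ann = annual_means(measurements, config.min_seasons, config.loq_policy)
    report["n_dwellings_with_annual_level"] = int(len(ann))
    screen = univariate_screen(ann, dwellings, config.exposure_screen_alpha,
                               config.exposure_forced_in)
    linear = fit_linear_exposure_model(ann, dwellings, screen["candidates"])
    logistic = fit_logistic_exposure_model(ann, dwellings, screen["candidates"])
    tertile = fit_multinomial_tertile_model(ann, dwellings, screen["candidates"])
    _json_dump(
        {
            "screen": {"candidates": list(screen["candidates"]),
                       "pvalues": screen["pvalues"]},
            "linear_log": linear.to_dict(),
            "logistic_median": logistic.to_dict(),
            "multinomial_tertile": tertile.to_dict(),
            "aic_table": {f.kind: round(f.aic, 4) for f in (linear, logistic, tertile)},
        },
        outdir / "exposure_model.json",
    )
    # Table-3-shaped output: one row per predictor level, OR and β side by side
    t3 = pd.DataFrame({
        "term": linear.params.index,
        "beta": np.round(np.asarray(linear.params), 4),
        "beta_p": np.round(np.asarray(linear.pvalues), 4),
    })
    or_tab = logistic.or_table.reindex(linear.params.index)
    t3["OR"] = np.round(or_tab["OR"].to_numpy(), 4)
    t3["OR_p"] = np.round(or_tab["p"].to_numpy(), 4)
    t3.to_csv(outdir / "exposure_model_table.csv", index=False)

    # -- cohort assignment -------------------------------------------------
    stage("assign")
    cohort_expo = assign_cohort_exposure(subjects, dwellings, linear)
    cohort_expo.round(4).to_csv(outdir / "cohort_exposure.csv", index=False)
    report["exposure_summary"] = {
        "median_assigned": float(np.median(cohort_expo["annual_level"])),
        "pct_high_all_year": float(100 * cohort_expo["high_all_year"].mean()),
    }

    # -- association models ------------------------------------------------
    stage("associate")
    expo_series = cohort_expo.set_index("subject_id")["annual_level"]
    hscreen = covariate_screen(subjects, config.health_screen_alpha,
                               config.health_forced_in)
    binary = fit_binary_lri(subjects, expo_series, hscreen["candidates"],
                            config.health_exposure_coding)
    multi = fit_multinomial_lri(subjects, expo_series, hscreen["candidates"],
                                config.health_exposure_coding)
    _json_dump(
        {
            "covariate_screen": {"candidates": list(hscreen["candidates"]),
                                 "pvalues": hscreen["pvalues"]},
            "binary_logistic": binary.to_dict(),
            "multinomial_logistic": multi.to_dict(),
        },
        outdir / "association_results.json",
    )
    # Table-4-shaped CSV: covariate rows, OR (CI) columns per outcome model
    rows = []
    multi_w = multi.table[multi.table["stratum"] == "wLRI"].set_index("term")
    for _, r in binary.table.iterrows():
        term = r["term"]
        rec = {"term": term,
               "LRI_OR": round(r["OR"], 3),
               "LRI_ci": f"({r['ci_low']:.2f}, {r['ci_high']:.2f})",
               "LRI_p": round(r["p"], 4)}
        if term in multi_w.index:
            w = multi_w.loc[term]
            rec.update({"wLRI_OR": round(w["OR"], 3),
                        "wLRI_ci": f"({w['ci_low']:.2f}, {w['ci_high']:.2f})",
                        "wLRI_p": round(w["p"], 4)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(outdir / "association_table.csv", index=False)
    report["associations"] = {
        "binary_fa_or_per_iqr": binary.fa_or_per_iqr.get("LRI"),
        "iqr_used": binary.iqr_used,
        "wLRI_fa_or_per_iqr": multi.fa_or_per_iqr.get("wLRI"),
    }

    # -- MCAR + Bayesian sensitivity ---------------------------------------
    stage("mcar")
    measured_dwelling_ids = set(measurements["dwelling_id"])
    flags = dwellings["dwelling_id"].isin(measured_dwelling_ids).astype(int)
    mcar = mcar_univariate_tests(dwellings, flags)
    _json_dump(mcar.to_dict(), outdir / "mcar_report.json")
    report["mcar_global_p"] = float(mcar.global_p)

    if config.bayes_enabled:
        stage("bayes")
        bres = fit_joint_bayes(
            subjects, dwellings, measurements,
            priors=config.bayes_priors,
            outcome=config.bayes_outcome,
            n_iter=config.bayes_n_iter,
            n_burnin=config.bayes_n_burnin,
            seed=config.seed,
            min_seasons=config.min_seasons,
            loq_policy=config.loq_policy,
            covariates=hscreen["candidates"],
        )
        _json_dump(
            {
                "iqr_used": bres.iqr_used,
                "acceptance": bres.acceptance,
                "warnings": bres.warnings_,
                "or_per_iqr": {k: v.to_dict() for k, v in bres.or_per_iqr.items()},
                "parameters": {k: v.to_dict() for k, v in bres.summaries.items()},
            },
            outdir / "posterior_summary.json",
        )
        long = bres.draws.reset_index(names="iteration").melt(
            id_vars="iteration", var_name="parameter", value_name="value"
        )
        long.to_csv(outdir / "draws.csv", index=False)
        report["bayes"] = {
            k: v.to_dict() for k, v in bres.or_per_iqr.items()
        }
        report["warnings"].extend(bres.warnings_)

    stage("report")
    report["artifact_checksums"] = {
        p.name: _checksum(p) for p in sorted(outdir.glob("*.csv"))
    }
    _json_dump(report, outdir / "run_report.json")
    return report
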