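"""File formats, configuration and the end-to-end pipeline driver.

The driver chains the full analysis: effort standardization, proportional
scaling, regression imputation of unsurveyed years, inverse matrix
estimation per stratum, hindcast verification from the held-out first
vector, the 100-year density-dependent forecast, and (optionally) the
disturbance ensemble and recruitment sweep. Every intermediate artifact is
written to the run directory together with a manifest (seed, config echo,
SHA-256 checksums), so a run is reproducible bitwise from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .disturbance import (DisturbanceRegime, ForecastConfig, TrajectoryEnsemble,
                          recruitment_sweep, run_ensemble)
from .inverse import decompose, solve_wood
from .preprocess import ImputationConfig
from .projection import (DensityDependence, RecruitmentSpec, hindcast_fit,
                         project_linear)
from .structure import (LifeCycleStructure, SizeClassScheme, write_matrix_csv,
                        write_structure_yaml)

__all__ = [
    "PipelineConfig",
    "read_survey_csv",
    "write_survey_csv",
    "write_trajectory_csv",
    "write_ensemble_csv",
    "run_pipeline",
]

logger = logging.getLogger("coraldemog")

SURVEY_META_COLUMNS = ("year", "stratum", "transects")


def write_survey_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "unit" not in out:
        out["unit"] = "raw"
    if "imputed" not in out:
        out["imputed"] = False
    out.to_csv(path, index=False)


def read_survey_csv(path, scheme: SizeClassScheme | None = None) -> pd.DataFrame:
    """Load and validate a long-format survey table.

    Required columns: year, stratum, transects plus one count column per
    size class; malformed rows are rejected with their row numbers.
    """
    scheme = scheme or SizeClassScheme()
    df = pd.read_csv(path, float_precision="round_trip")
    required = list(SURVEY_META_COLUMNS) + scheme.column_names()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "unit" not in df:
        df["unit"] = "raw"
    if "imputed" not in df:
        df["imputed"] = False
    df["imputed"] = df["imputed"].astype(bool)
    counts = df[scheme.column_names()].to_numpy(dtype=float)
    bad = np.where(np.any(counts < 0, axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{path}: negative counts in rows {(bad + 2).tolist()} "
            "(1-based, counting the header)")
    dup = df.duplicated(subset=["year", "stratum"], keep=False)
    if dup.any():
        rows = (np.where(dup)[0] + 2).tolist()
        raise ValueError(f"{path}: duplicate (year, stratum) in rows {rows}")
    return df


def write_trajectory_csv(series: np.ndarray, scheme: SizeClassScheme, path,
                         reference_area_m2: float = 300.0) -> None:
    """Tidy per-step trajectory: step, class, abundance, cover_pct."""
    import math

    d = np.asarray(scheme.representative_diameter_cm)
    area = math.pi * (d / 200.0) ** 2
    rows = []
    for t, n in enumerate(np.asarray(series, dtype=float)):
        for j, lab in enumerate(scheme.class_labels):
            rows.append({"step": t, "class": lab, "abundance": n[j],
                         "cover_pct": 100.0 * n[j] * area[j] / reference_area_m2})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ensemble_csv(ens: TrajectoryEnsemble, real_path, summary_path) -> None:
    steps = np.arange(ens.cover.shape[1])
    tidy = pd.DataFrame({
        "realization": np.repeat(np.arange(ens.n_realizations), steps.size),
        "step": np.tile(steps, ens.n_realizations),
        "cover_pct": ens.cover.reshape(-1),
    })
    tidy.to_csv(real_path, index=False)
    pd.DataFrame({
        "step": steps,
        "mean": ens.mean_cover,
        "q05": ens.quantiles["q05"],
        "q50": ens.quantiles["q50"],
        "q95": ens.quantiles["q95"],
    }).to_csv(summary_path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a full run, with study defaults where values are known."""

    survey_csv: str
    output_dir: str
    structure: LifeCycleStructure = field(
        default_factory=LifeCycleStructure.default_graph)
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)
    reference_transects: int = 6
    imputation: ImputationConfig = ImputationConfig(
        target_years=(2011, 2012), window_years=(2010, 2013, 2014))
    sc1_correction: float = 1.0  # multiply SC1 by this before scaling (2.0 undoes 50% under-detection)
    use_years: tuple[int, ...] | None = None  # solver fit window; None = all but first
    ridge: float = 0.0
    recruitment: RecruitmentSpec = RecruitmentSpec()
    density: DensityDependence = DensityDependence()
    reference_area_m2: float = 300.0
    steps: int = 100
    regime: DisturbanceRegime | None = DisturbanceRegime()
    realizations: int = 500
    sweep_means: tuple[float, ...] = ()
    sweep_reps: int = 100
    master_seed: int = 0
    log_level: str = "INFO"


def _stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (documented splitting rule)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts plus a manifest.

    Returns the run directory. A rerun with the same config reproduces all
    stochastic outputs bitwise (the master seed spawns per-stage,
    per-stratum child seeds).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme

    logger.info("stage=read survey=%s", config.survey_csv)
    survey = read_survey_csv(config.survey_csv, scheme)

    if config.sc1_correction != 1.0:
        sc1 = scheme.column_names()[0]
        survey = survey.copy()
        survey[sc1] = survey[sc1] * config.sc1_correction
        logger.info("stage=sc1-correction factor=%s", config.sc1_correction)

    logger.info("stage=standardize reference_transects=%d",
                config.reference_transects)
    standardized = preprocess.standardize_effort(
        survey, config.reference_transects, scheme)
    write_survey_csv(standardized, out / "standardized.csv")

    proportional = preprocess.to_proportional_frame(standardized, scheme)
    imputed = preprocess.impute_missing_years(proportional, config.imputation,
                                              scheme)
    write_survey_csv(imputed, out / "proportional_imputed.csv")
    logger.info("stage=impute targets=%s window=%s",
                config.imputation.target_years, config.imputation.window_years)

    report: dict = {"strata": {}, "master_seed": config.master_seed}
    for stratum in imputed["stratum"].unique():
        vectors, years = preprocess.series_vectors(imputed, stratum, scheme=scheme)
        if config.use_years is not None:
            fit_years = [y for y in years if y in config.use_years]
        else:
            fit_years = years[1:]  # hold out the first vector for hindcast
        fit_vectors, _ = preprocess.series_vectors(
            imputed, stratum, years=fit_years, scheme=scheme)
        logger.info("stage=solve stratum=%s fit_years=%s ridge=%s",
                    stratum, fit_years, config.ridge)
        solved = solve_wood(fit_vectors, config.structure, ridge=config.ridge,
                            scheme=scheme)
        write_matrix_csv(solved.matrix, out / f"matrix_{stratum}.csv",
                         labels=scheme.class_labels)

        # hindcast from the held-out first vector with the deterministic
        # recruit sequence
        hind_steps = len(years) - 1
        predicted = project_linear(
            solved.matrix, vectors[0], hind_steps,
            recruitment=RecruitmentSpec.deterministic(
                config.recruitment.deterministic_sequence))
        fit = hindcast_fit(predicted[1:], vectors[1:])
        logger.info("stage=hindcast stratum=%s r2=%.4f", stratum, fit.r_squared)

        decomp = decompose(solved.matrix)
        fc = ForecastConfig(decomp=decomp, dd=config.density,
                            n0=vectors[0], recruitment=config.recruitment,
                            scheme=scheme,
                            reference_area_m2=config.reference_area_m2,
                            horizon=config.steps)
        seed_fc = _stage_seed(config.master_seed, f"forecast:{stratum}")
        forecast = run_ensemble(fc, regime=None, realizations=1,
                                master_seed=seed_fc)
        write_trajectory_csv(forecast.abundance[0], scheme,
                             out / f"forecast_{stratum}.csv",
                             config.reference_area_m2)
        entry = {
            "fit_years": fit_years,
            "rss": solved.rss,
            "identifiable": solved.identifiable,
            "hindcast_r2": fit.r_squared,
            "forecast_seed": seed_fc,
            "final_cover_pct": float(forecast.mean_cover[-1]),
            "density_mode": config.density.mode,
        }

        if config.regime is not None:
            seed_dist = _stage_seed(config.master_seed, f"disturb:{stratum}")
            logger.info("stage=disturb stratum=%s reps=%d seed=%d",
                        stratum, config.realizations, seed_dist)
            ens = run_ensemble(fc, regime=config.regime,
                               realizations=config.realizations,
                               master_seed=seed_dist)
            write_ensemble_csv(ens, out / f"ensemble_{stratum}.csv",
                               out / f"ensemble_summary_{stratum}.csv")
            entry["disturbance_seed"] = seed_dist
            entry["mean_cover_at_horizon"] = float(ens.mean_cover[-1])
            entry["persistent"] = ens.persistent

        if config.sweep_means:
            seed_sw = _stage_seed(config.master_seed, f"sweep:{stratum}")
            table, line = recruitment_sweep(fc, config.sweep_means,
                                            reps=config.sweep_reps,
                                            master_seed=seed_sw)
            table.to_csv(out / f"sweep_{stratum}.csv", index=False)
            (out / f"sweep_fit_{stratum}.json").write_text(json.dumps(line))
            entry["sweep_seed"] = seed_sw
            entry["sweep_fit"] = line

        report["strata"][str(stratum)] = entry

    write_structure_yaml(config.structure, out / "structure.yaml",
                         labels=scheme.class_labels)
    (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "master_seed": config.master_seed,
        "config": _config_echo(config),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("stage=done artifacts=%d dir=%s", len(manifest["files"]), out)
    return out


def _config_echo(config: PipelineConfig) -> dict:
    """JSON-serializable echo of the configuration for the manifest."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(str(v) for v in o)
        return str(o)

    raw = asdict(config)
    return json.loads(json.dumps(raw, default=default))


def load_config_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of plain options."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("survey_csv", "output_dir", "reference_transects",
                "sc1_correction", "ridge", "reference_area_m2", "steps",
                "realizations", "sweep_reps", "master_seed", "log_level"):
        if key in doc:
            kwargs[key] = doc[key]
    if "structure_yaml" in doc:
        from .structure import read_structure_yaml
        kwargs["structure"] = read_structure_yaml(doc["structure_yaml"])
    if "use_years" in doc and doc["use_years"] is not None:
        kwargs["use_years"] = tuple(int(y) for y in doc["use_years"])
    if "imputation" in doc:
        imp = doc["imputation"]
        kwargs["imputation"] = ImputationConfig(
            target_years=tuple(imp["target_years"]),
            window_years=tuple(imp["window_years"]),
            clip_negative=imp.get("clip_negative", True))
    if "recruitment" in doc:
        rec = doc["recruitment"]
        kwargs["recruitment"] = RecruitmentSpec(
            deterministic_sequence=tuple(rec.get("deterministic_sequence",
                                                 (5, 0, 0, 3, 0))),
            gaussian_mean=rec.get("gaussian_mean", 25.0),
            gaussian_variance=rec.get("gaussian_variance", 25.0))
    if "density" in doc:
        den = doc["density"]
        kwargs["density"] = DensityDependence(
            b=tuple(den.get("b", (0, 0, 0.001, 0.001, 0.001))),
            mode=den.get("mode", "inflow"))
    if "regime" in doc:
        reg = doc["regime"]
        if reg is None:
            kwargs["regime"] = None
        else:
            kwargs["regime"] = DisturbanceRegime(
                interval_min_yr=reg.get("interval_min_yr", 10.0),
                interval_max_yr=reg.get("interval_max_yr", 20.0),
                kill_min=reg.get("kill_min", 0.0),
                kill_max=reg.get("kill_max", 1.0))
    if "sweep_means" in doc:
        kwargs["sweep_means"] = tuple(float(m) for m in doc["sweep_means"])
    return PipelineConfig(**kwargs)
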