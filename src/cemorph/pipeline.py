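"""End-to-end orchestration: simulate (or load) -> reliability -> atrophy -> SCN.

Writes the full analysis bundle into an output directory:

* ``cohort.csv`` / ``truth.csv`` — measured and noise-free tables (full precision)
* ``reliability.csv`` / ``reliability.json`` — paired agreement per method x subset
* ``rates.csv`` — per-patient atrophy rates (global scope)
* ``table1.csv`` — group mean rates and effect sizes
* ``regional_rates.csv`` — per-region group mean rates
* ``scn_curves.csv`` — efficiency curves with subsample SD bands
* ``manifest.json`` — config echo, seed, config hash, package versions

Every CSV carries a ``#`` header with the master seed and config hash;
re-running with identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .atrophy import compute_atrophy_rates, group_effect_table, regional_atrophy_map
from .exceptions import ConfigurationError
from .io import config_hash, read_morph_table, write_morph_table
from .reliability import reliability_report
from .scn import default_tau_grid, residualize_age, subsample_band
from .synthetic import (
    CohortConfig,
    MeasurementModel,
    VisitSchedule,
    default_study_config,
    simulate_study,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ARTIFACTS = [
    "cohort.csv",
    "reliability.csv",
    "reliability.json",
    "rates.csv",
    "table1.csv",
    "regional_rates.csv",
    "scn_curves.csv",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    mode: str = "simulate"  # "simulate" | "load"
    cohort_csv: str | None = None  # input table in load mode
    cohort: CohortConfig | None = None  # None -> packaged defaults
    models: list[MeasurementModel] | None = None
    min_timepoints: int = 3
    tau_star: float = 0.5
    tau_step: float = 0.01
    fraction: float = 0.8
    reps: int = 1000
    residualize: str = "per-group"
    out_dir: str = "cemorph_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if not self.cohort_csv:
                raise ConfigurationError("load mode requires cohort_csv")
            if not Path(self.cohort_csv).exists():
                raise ConfigurationError(f"cohort_csv not found: {self.cohort_csv}")
        if not 0 < self.fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")
        if self.reps < 0:
            raise ConfigurationError("reps must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a RunConfig from a key-value YAML file.

        Keys mirror the field names; ``cohort`` and ``models`` accept
        nested mappings mirroring CohortConfig / MeasurementModel fields.
        """
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        models = raw.pop("models", None)
        cfg = cls(**raw)
        if cohort is not None:
            for key in ("sessions_rrms", "sessions_ppms"):
                if key in cohort and isinstance(cohort[key], dict):
                    cohort[key] = VisitSchedule(**cohort[key])
            for key in ("roi_names", "baseline_age_range", "factor_weight_range"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            cfg.cohort = CohortConfig(**cohort)
        if models is not None:
            cfg.models = [MeasurementModel(**m) for m in models]
        return cfg


def _write_report_csv(df: pd.DataFrame, path: Path, seed: int, chash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={seed}\n# config_hash={chash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write all artifacts.

    Returns a mapping artifact name -> path.  Any stage failure raises with
    the stage named in the log.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = config.cohort
    models = config.models
    if cohort_cfg is None or models is None:
        default_cfg, default_models = default_study_config()
        cohort_cfg = cohort_cfg or dataclasses.replace(default_cfg, seed=config.seed)
        models = models or default_models

    run_dict = config.to_dict()
    for key in ("out_dir", "log_level"):  # irrelevant to the results
        run_dict.pop(key, None)
    chash = config_hash(
        {
            "run": run_dict,
            "cohort": dataclasses.asdict(cohort_cfg),
            "models": [dataclasses.asdict(m) for m in models],
        }
    )
    paths: dict[str, Path] = {}

    logger.info("stage: %s", config.mode)
    if config.mode == "simulate":
        truth, measured = simulate_study(cohort_cfg, models)
        write_morph_table(truth, out / "truth.csv", seed=config.seed, cfg_hash=chash)
        write_morph_table(measured, out / "cohort.csv", seed=config.seed, cfg_hash=chash)
        paths["truth.csv"] = out / "truth.csv"
    else:
        measured = read_morph_table(config.cohort_csv)
        write_morph_table(measured, out / "cohort.csv", seed=config.seed, cfg_hash=chash)
    paths["cohort.csv"] = out / "cohort.csv"

    logger.info("stage: reliability")
    rel = reliability_report(measured)
    _write_report_csv(rel, out / "reliability.csv", config.seed, chash)
    with open(out / "reliability.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"seed": config.seed, "config_hash": chash, "results": rel.to_dict("records")},
            fh,
            indent=2,
        )
    paths["reliability.csv"] = out / "reliability.csv"
    paths["reliability.json"] = out / "reliability.json"

    logger.info("stage: atrophy")
    rates = compute_atrophy_rates(measured, min_timepoints=config.min_timepoints)
    _write_report_csv(rates, out / "rates.csv", config.seed, chash)
    table1 = group_effect_table(rates)
    _write_report_csv(table1, out / "table1.csv", config.seed, chash)
    regional = regional_atrophy_map(measured, min_timepoints=config.min_timepoints)
    _write_report_csv(regional, out / "regional_rates.csv", config.seed, chash)
    paths["rates.csv"] = out / "rates.csv"
    paths["table1.csv"] = out / "table1.csv"
    paths["regional_rates.csv"] = out / "regional_rates.csv"

    logger.info("stage: scn")
    grid = default_tau_grid() if config.tau_step == 0.01 else _grid(config.tau_step)
    curve_rows = []
    methods = [m for m in measured["method"].unique() if m != "TRUE"]
    for method in methods:
        for itype in ("pre", "CE"):
            for group in ("PPMS", "RRMS"):
                res = residualize_age(
                    measured, method=method, image_type=itype, group=group
                )
                curve = subsample_band(
                    res,
                    fraction=config.fraction,
                    reps=config.reps,
                    tau_grid=grid,
                    seed=config.seed,
                    group=group,
                    method=method,
                    image_type=itype,
                )
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "group": group,
                            "method": method,
                            "image_type": itype,
                            "tau": curve.thresholds,
                            "e_glob": curve.e_glob,
                            "band_sd": curve.band_sd,
                        }
                    )
                )
    curves = pd.concat(curve_rows, ignore_index=True)
    _write_report_csv(curves, out / "scn_curves.csv", config.seed, chash)
    paths["scn_curves.csv"] = out / "scn_curves.csv"

    manifest = {
        "seed": config.seed,
        "config_hash": chash,
        "config": config.to_dict(),
        "cohort_config": dataclasses.asdict(cohort_cfg),
        "models": [dataclasses.asdict(m) for m in models],
        "versions": {"cemorph": __version__, "pandas": pd.__version__},
        "artifacts": sorted(str(p.name) for p in paths.values()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest.json"] = out / "manifest.json"
    logger.info("pipeline complete: %d artifacts in %s", len(paths), out)
    return paths


def _grid(step: float):
    import numpy as np

    n = int(np.floor(1.0 / step))
    return np.round(np.arange(n) * step, 10)
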