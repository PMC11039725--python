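"""End-to-end orchestration: simulate -> indicators -> weights -> DEA -> forecast.

``run_pipeline`` executes each stage in order, writes one artifact per
stage plus a manifest (seed, config hash, per-artifact checksums) and is
idempotent: identical inputs and seed reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .dea import score_series
from .forecast import ForecastConfig, forecast_series
from .indicators import build_panel
from .synthetic import FleetConfig, generate_dataset
from .weighting import (ahp_weights, consistency_ratio, critic_weights,
                        game_combine, minmax_standardize)

__all__ = ["RunConfig", "PipelineError", "DEFAULT_DIRECTIONS",
           "compute_combined_weights", "run_pipeline"]

log = logging.getLogger("fleetdea")

#: smaller-is-better indicators are "cost"-type for standardization
DEFAULT_DIRECTIONS = {"X1": "benefit", "X2": "benefit", "X3": "cost",
                      "X4": "cost", "X5": "benefit", "X6": "cost",
                      "X7": "benefit", "X8": "cost"}

INPUT_GROUP = ("X1", "X2", "X3", "X4")
OUTPUT_GROUP = ("X5", "X6", "X7", "X8")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    When ``events_path``/``costs_path`` are unset the fleet simulator is run
    with ``fleet`` (seeded from ``seed``) instead of reading files.
    """

    out_dir: str | Path = "fleetdea_run"
    events_path: str | Path | None = None
    costs_path: str | Path | None = None
    judgement_input_path: str | Path | None = None
    judgement_output_path: str | Path | None = None
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    dea_mode: str = "pooled"
    use_cone: bool = True
    fleet: FleetConfig = field(default_factory=FleetConfig)
    forecast: ForecastConfig = field(default_factory=ForecastConfig)
    seed: int = 42
    log_level: str = "INFO"


def compute_combined_weights(panel: pd.DataFrame, jm_in, jm_out,
                             directions: dict = DEFAULT_DIRECTIONS) -> dict:
    """AHP, improved-CRITIC and game-combined weights per indicator group.

    Returns a dict keyed "input"/"output", each holding the three weight
    vectors, the combination coefficients and the AHP consistency result.
    """
    out = {}
    for group, cols, jm in (("input", INPUT_GROUP, jm_in),
                            ("output", OUTPUT_GROUP, jm_out)):
        ahp = ahp_weights(jm, group=group)
        cons = consistency_ratio(jm, ahp)
        dirs = [directions[c] for c in cols]
        z = minmax_standardize(panel.loc[:, list(cols)].to_numpy(float),
                               dirs, labels=cols)
        breakdown, critic = critic_weights(z, labels=cols, group=group)
        lam, game = game_combine(ahp, critic)
        out[group] = {"labels": cols, "ahp": ahp, "critic": critic,
                      "game": game, "lambda": lam, "consistency": cons,
                      "critic_breakdown": breakdown}
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns {artifact name: path} plus in-memory results."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.time()

    # -- stage: data -----------------------------------------------------
    stage = "data"
    try:
        if config.events_path and config.costs_path:
            events = fio.read_events(config.events_path)
            costs = fio.read_costs(config.costs_path)
        else:
            fleet = dataclasses.replace(config.fleet, seed=config.seed)
            events, costs = generate_dataset(fleet)
            fio.write_events(events, out_dir / "events.csv")
            fio.write_costs(costs, out_dir / "costs.csv")
        log.info("stage data: %d events, %d cost rows (%.1fs)",
                 len(events), len(costs), time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: indicators ----------------------------------------------
    stage = "indicators"
    try:
        panel = build_panel(events, costs)
        fio.write_panel(panel, out_dir / "panel.csv")
        artifacts["panel"] = out_dir / "panel.csv"
        log.info("stage indicators: %d device-months", len(panel))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: weighting ------------------------------------------------
    stage = "weighting"
    try:
        if config.judgement_input_path and config.judgement_output_path:
            jm_in = fio.read_judgement_matrix(config.judgement_input_path)
            jm_out = fio.read_judgement_matrix(config.judgement_output_path)
        else:
            jm_in, jm_out = fio.reference_judgement_matrices()
        weights = compute_combined_weights(panel, jm_in, jm_out,
                                           config.directions)
        payload = {}
        for group, res in weights.items():
            payload[group] = {
                "labels": list(res["labels"]),
                "ahp": [float(v) for v in res["ahp"].weights],
                "critic": [float(v) for v in res["critic"].weights],
                "game": [float(v) for v in res["game"].weights],
                "lambda": [float(v) for v in res["lambda"]],
                "CR": res["consistency"].cr,
            }
        (out_dir / "weights.json").write_text(json.dumps(payload, indent=2))
        artifacts["weights"] = out_dir / "weights.json"
        log.info("stage weighting: input CR=%.4f output CR=%.4f",
                 weights["input"]["consistency"].cr,
                 weights["output"]["consistency"].cr)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: dea ------------------------------------------------------
    stage = "dea"
    try:
        scores = score_series(
            panel,
            input_weights=weights["input"]["game"] if config.use_cone else None,
            output_weights=weights["output"]["game"] if config.use_cone else None,
            mode=config.dea_mode, use_cone=config.use_cone)
        fio.write_scores(scores, out_dir / "scores.csv")
        artifacts["scores"] = out_dir / "scores.csv"
        log.info("stage dea: %d DMUs scored (mode=%s, cone=%s)",
                 len(scores), config.dea_mode, config.use_cone)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: forecast -------------------------------------------------
    stage = "forecast"
    try:
        col = "score_cone" if config.use_cone else "score_ccr"
        fc_payload = {}
        for device, g in scores.groupby("device_id"):
            series = g.sort_values("month")[col].to_numpy(float)
            report = forecast_series(series, config.forecast)
            fc_payload[device] = {
                "mse": report.mse, "rmse": report.rmse, "mae": report.mae,
                "mape": report.mape, "r2": report.r2,
                "final_training_loss": report.final_training_loss,
                "predictions": [float(v) for v in report.predictions],
                "actuals": [float(v) for v in report.actuals],
                "attention": np.asarray(report.attention).tolist(),
            }
        (out_dir / "forecast.json").write_text(json.dumps(fc_payload, indent=2))
        artifacts["forecast"] = out_dir / "forecast.json"
        log.info("stage forecast: %d devices", len(fc_payload))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- manifest ----------------------------------------------------------
    cfg_repr = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()},
        sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in artifacts.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = out_dir / "manifest.json"
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return {"artifacts": artifacts, "panel": panel, "weights": weights,
            "scores": scores, "forecast": fc_payload, "manifest": manifest}
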