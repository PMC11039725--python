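"""CSV/JSON/YAML schemas and validated readers/writers.

All tables are plain UTF-8 CSV with a mandatory header row, ISO-8601
timestamps at minute precision, months as ``YYYY-MM`` and decimal points.
Every writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .weighting import JudgementMatrix, WeightVector

__all__ = [
    "SchemaError",
    "read_events", "write_events",
    "read_costs", "write_costs",
    "read_panel", "write_panel",
    "read_scores", "write_scores",
    "read_judgement_matrix", "write_judgement_matrix",
    "reference_judgement_matrices",
    "write_weights_json", "read_weights_json",
    "read_run_config",
]

EVENT_COLUMNS = ("device_id", "booked_at", "started_at", "finished_at",
                 "report_at", "revenue")
COST_COLUMNS = ("device_id", "month", "operating_cost", "depreciation",
                "energized_minutes")
PANEL_COLUMNS = ("device_id", "month", "X1", "X2", "X3", "X4",
                 "X5", "X6", "X7", "X8", "n_exams")

_TS_FORMAT = "%Y-%m-%dT%H:%M"
_DATA_DIR = Path(__file__).parent / "data"


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...],
                     path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    for col in ("booked_at", "started_at", "finished_at", "report_at"):
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise SchemaError(f"{path}: malformed timestamp in {col!r} "
                              f"at line {row}: {df[col][bad].iloc[0]!r}")
        df[col] = parsed
    order_ok = ((df["booked_at"] <= df["started_at"])
                & (df["started_at"] < df["finished_at"])
                & (df["finished_at"] <= df["report_at"]))
    if not order_ok.all():
        row = int(np.flatnonzero(~order_ok)[0]) + 2
        raise SchemaError(f"{path}: timestamp ordering violated at line {row}")
    if (df["revenue"] < 0).any():
        row = int(np.flatnonzero(df["revenue"] < 0)[0]) + 2
        raise SchemaError(f"{path}: negative revenue at line {row}")
    return df.sort_values(["device_id", "started_at"]).reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    for col in ("booked_at", "started_at", "finished_at", "report_at"):
        out[col] = pd.to_datetime(out[col]).dt.strftime(_TS_FORMAT)
    out.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_costs(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"month": str})
    _require_columns(df, COST_COLUMNS, path)
    bad = ~df["month"].str.match(r"^\d{4}-\d{2}$")
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise SchemaError(f"{path}: month must be YYYY-MM at line {row}")
    for col, minimum in (("operating_cost", 0.0), ("energized_minutes", 0.0)):
        if (df[col] <= minimum).any():
            row = int(np.flatnonzero(df[col] <= minimum)[0]) + 2
            raise SchemaError(f"{path}: non-positive {col} at line {row}")
    return df.sort_values(["device_id", "month"]).reset_index(drop=True)


def write_costs(costs: pd.DataFrame, path: str | Path) -> None:
    costs.loc[:, list(COST_COLUMNS)].to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"month": str})
    _require_columns(df, PANEL_COLUMNS, path)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.loc[:, list(PANEL_COLUMNS)].to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"month": str})
    _require_columns(df, ("device_id", "month", "score_ccr"), path)
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def read_judgement_matrix(path: str | Path) -> JudgementMatrix:
    """Square CSV whose header row carries the indicator labels."""
    path = Path(path)
    df = pd.read_csv(path)
    labels = tuple(str(c) for c in df.columns)
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise SchemaError(f"{path}: judgement matrix must be square, "
                          f"got {a.shape[0]} rows x {a.shape[1]} columns")
    try:
        return JudgementMatrix(values=a, labels=labels)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_judgement_matrix(j: JudgementMatrix, path: str | Path) -> None:
    pd.DataFrame(j.values, columns=list(j.labels)).to_csv(path, index=False)


def reference_judgement_matrices() -> tuple[JudgementMatrix, JudgementMatrix]:
    """Bundled expert pairwise-comparison matrices for the eight-indicator
    MRI evaluation system (input group X1-X4, output group X5-X8)."""
    return (read_judgement_matrix(_DATA_DIR / "judgement_input.csv"),
            read_judgement_matrix(_DATA_DIR / "judgement_output.csv"))


def write_weights_json(path: str | Path, group: str, labels: tuple[str, ...],
                       ahp: np.ndarray, critic: np.ndarray, game: np.ndarray,
                       lam: np.ndarray, cr: float) -> None:
    payload = {"group": group, "labels": list(labels),
               "ahp": [float(v) for v in ahp],
               "critic": [float(v) for v in critic],
               "game": [float(v) for v in game],
               "lambda": [float(v) for v in lam],
               "CR": float(cr)}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_weights_json(path: str | Path) -> dict:
    """Weights artifact: either one group ({group, labels, ahp, ...}) or the
    two-group layout {"input": {...}, "output": {...}} the pipeline emits."""
    payload = json.loads(Path(path).read_text())
    if "input" in payload and "output" in payload:
        groups = payload.values()
    elif "group" in payload:
        groups = [payload]
    else:
        raise SchemaError(f"{path}: expected 'input'/'output' groups or a "
                          "single 'group' entry")
    for entry in groups:
        for key in ("labels", "ahp", "critic", "game"):
            if key not in entry:
                raise SchemaError(f"{path}: missing key {key!r}")
    return payload


def read_run_config(path: str | Path) -> dict:
    """Run configuration as YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise SchemaError(f"{path}: config must be .yaml, .yml or .json")
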