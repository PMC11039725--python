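"""The eight-indicator device-month panel and the Pearson correlation screen.

Inputs (resource side):

* ``X1`` utilization rate: ``(tau + 2) * n_exams / energized_minutes`` with
  ``tau`` the mean exam duration in minutes and 2 minutes of preparation
  per exam — a dimensionless load ratio near 1 at saturation.
* ``X2`` average daily working hours: total scanning hours divided by the
  calendar days of the month.
* ``X3`` operating cost for the month (energy, maintenance, staffing).
* ``X4`` average cost per exam: ``(operating_cost + depreciation) / n_exams``.

Outputs (service side):

* ``X5`` inspection revenue (sum of per-exam revenue).
* ``X6`` mean appointment wait in minutes (booking to scan start).
* ``X7`` cost-benefit ratio ``X5 / X3``.
* ``X8`` mean report wait in minutes (scan end to report ready).
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PREP_MINUTES",
    "INDICATOR_COLUMNS",
    "CorrelationReport",
    "compute_input_indicators",
    "compute_output_indicators",
    "build_panel",
    "correlation_matrix",
]

PREP_MINUTES = 2.0  # fixed per-exam preparation time folded into utilization
INDICATOR_COLUMNS = ("X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8")


@dataclass(frozen=True)
class CorrelationReport:
    labels: tuple[str, ...]
    r: pd.DataFrame        # Pearson correlations, symmetric, unit diagonal
    p: pd.DataFrame        # two-sided p-values (NaN on the diagonal)
    degenerate: tuple[str, ...] = ()   # constant columns, r undefined


def _month_slice(events: pd.DataFrame, device: str, month: str) -> pd.DataFrame:
    ev = events[(events["device_id"] == device)
                & (events["started_at"].dt.strftime("%Y-%m") == month)]
    return ev


def _cost_row(costs: pd.DataFrame, device: str, month: str) -> pd.Series:
    row = costs[(costs["device_id"] == device) & (costs["month"] == month)]
    if row.empty:
        raise KeyError(f"no cost record for device {device!r} month {month!r}")
    return row.iloc[0]


def _days_in_month(month: str) -> int:
    y, m = (int(p) for p in month.split("-"))
    return calendar.monthrange(y, m)[1]


def compute_input_indicators(events: pd.DataFrame, costs: pd.DataFrame,
                             month: str, device: str) -> tuple[float, float, float, float]:
    """(X1, X2, X3, X4) for one device-month."""
    ev = _month_slice(events, device, month)
    if ev.empty:
        raise ValueError(f"no exams for device {device!r} in {month!r}")
    cost = _cost_row(costs, device, month)
    if cost["energized_minutes"] <= 0:
        raise ValueError("energized_minutes must be positive")
    n = len(ev)
    durations_min = (ev["finished_at"] - ev["started_at"]).dt.total_seconds() / 60.0
    tau = float(durations_min.mean())
    x1 = (tau + PREP_MINUTES) * n / float(cost["energized_minutes"])
    x2 = float(durations_min.sum()) / 60.0 / _days_in_month(month)
    x3 = float(cost["operating_cost"])
    x4 = (float(cost["operating_cost"]) + float(cost["depreciation"])) / n
    return x1, x2, x3, x4


def compute_output_indicators(events: pd.DataFrame, costs: pd.DataFrame,
                              month: str, device: str) -> tuple[float, float, float, float]:
    """(X5, X6, X7, X8) for one device-month."""
    ev = _month_slice(events, device, month)
    if ev.empty:
        raise ValueError(f"no exams for device {device!r} in {month!r}")
    cost = _cost_row(costs, device, month)
    if cost["operating_cost"] == 0:
        raise ValueError("operating_cost is zero: cost-benefit ratio undefined")
    n = len(ev)
    x5 = float(ev["revenue"].sum())
    x6 = float((ev["started_at"] - ev["booked_at"]).dt.total_seconds().sum() / 60.0) / n
    x7 = x5 / float(cost["operating_cost"])
    x8 = float((ev["report_at"] - ev["finished_at"]).dt.total_seconds().sum() / 60.0) / n
    return x5, x6, x7, x8


def build_panel(events: pd.DataFrame, costs: pd.DataFrame) -> pd.DataFrame:
    """Indicator panel over every (device, month) with at least one exam.

    Device-months without exams are dropped with a warning (DEA needs
    strictly positive inputs).  Returns columns device_id, month, X1..X8,
    n_exams, sorted by device then month.
    """
    rows = []
    for _, crow in costs.iterrows():
        device, month = crow["device_id"], crow["month"]
        ev = _month_slice(events, device, month)
        if ev.empty:
            warnings.warn(f"device {device!r} month {month!r} has no exams; "
                          "excluded from panel", stacklevel=2)
            continue
        x1, x2, x3, x4 = compute_input_indicators(events, costs, month, device)
        x5, x6, x7, x8 = compute_output_indicators(events, costs, month, device)
        rows.append({"device_id": device, "month": month,
                     "X1": x1, "X2": x2, "X3": x3, "X4": x4,
                     "X5": x5, "X6": x6, "X7": x7, "X8": x8,
                     "n_exams": len(ev)})
    panel = pd.DataFrame(rows)
    if panel.empty:
        raise ValueError("no scoreable device-months in the inputs")
    return panel.sort_values(["device_id", "month"]).reset_index(drop=True)


def correlation_matrix(panel: pd.DataFrame,
                       columns: tuple[str, ...] = INDICATOR_COLUMNS) -> CorrelationReport:
    """Pairwise Pearson correlation screen over the indicator columns.

    Constant columns are flagged and their pairs reported as NaN rather than
    raising; the screen is descriptive, not a filter.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 device-month rows for correlations")
    x = panel.loc[:, list(columns)].to_numpy(dtype=float)
    k = len(columns)
    constant = [columns[j] for j in range(k) if np.ptp(x[:, j]) == 0]
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                r[i, j] = 1.0
                continue
            if columns[i] in constant or columns[j] in constant:
                continue
            rij, pij = stats.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    labels = tuple(columns)
    return CorrelationReport(
        labels=labels,
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
        degenerate=tuple(constant),
    )
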