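"""Seeded synthetic MRI-fleet operation data.

Emulates a small hospital imaging fleet (by default 4 scanners observed for
24 months) at the event level: every examination carries booking, scan
start/end and report-ready timestamps plus revenue, and every device-month
carries operating cost, depreciation and energized running time.  One device
may be flagged "high-efficiency": its throughput is scaled up and its scan
durations and waiting times down by the same multiplier, mimicking a scanner
with a faster sweep sequence — tariffs are untouched.

Distributional choices (positive, right-skewed, few parameters):

* exam duration: truncated normal (lower bound 10 min);
* appointment lead and report delay: gamma (shape 2);
* monthly operating cost: base x lognormal noise.

All draws flow from a single :func:`numpy.random.default_rng` generator, so
the output is a pure function of the configuration (which embeds the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["FleetConfig", "generate_dataset"]

_MIN_EXAM_MINUTES = 10.0


@dataclass(frozen=True)
class FleetConfig:
    """Parameters of the simulated fleet.

    Durations are minutes, money is in an arbitrary fixed currency unit.
    ``efficiency_multipliers`` has one entry per device; at most one entry
    may exceed 1 (the planted high-efficiency device).
    """

    n_devices: int = 4
    n_months: int = 24
    start_month: str = "2022-01"
    mean_exams_per_day: float = 18.0
    mean_exam_minutes: float = 28.0
    sd_exam_minutes: float = 8.0
    prep_minutes: float = 2.0
    appointment_lead_mean: float = 2160.0   # 1.5 days, gamma-distributed
    appointment_lead_shape: float = 2.0
    report_delay_mean: float = 1440.0       # 1 day, gamma-distributed
    report_delay_shape: float = 2.0
    tariff_per_exam: float = 600.0
    revenue_sigma: float = 0.10             # lognormal spread around the tariff
    operating_cost_base: float = 150_000.0
    operating_cost_sigma: float = 0.15
    depreciation_per_month: float = 80_000.0
    energized_minutes_per_day: float = 660.0  # 11 h powered-on per day
    efficiency_multipliers: tuple[float, ...] = (1.3, 1.0, 0.95, 0.9)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_devices < 1 or self.n_months < 1:
            raise ValueError("n_devices and n_months must be >= 1")
        if self.mean_exams_per_day <= 0:
            raise ValueError("mean_exams_per_day must be positive")
        positive = ("mean_exam_minutes", "sd_exam_minutes", "prep_minutes",
                    "appointment_lead_mean", "report_delay_mean",
                    "tariff_per_exam", "operating_cost_base",
                    "energized_minutes_per_day")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depreciation_per_month < 0:
            raise ValueError("depreciation_per_month must be >= 0")
        if len(self.efficiency_multipliers) != self.n_devices:
            raise ValueError("one efficiency multiplier per device required")
        if any(g <= 0 for g in self.efficiency_multipliers):
            raise ValueError("efficiency multipliers must be positive")
        if sum(g > 1.0 for g in self.efficiency_multipliers) > 1:
            raise ValueError("at most one device may be flagged high-efficiency "
                             "(multiplier > 1)")

    @property
    def device_ids(self) -> tuple[str, ...]:
        return tuple(chr(ord("A") + k) for k in range(self.n_devices))

    def with_seed(self, seed: int) -> "FleetConfig":
        return replace(self, seed=seed)


def _months(config: FleetConfig) -> list[pd.Period]:
    start = pd.Period(config.start_month, freq="M")
    return [start + k for k in range(config.n_months)]


def generate_dataset(config: FleetConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the fleet; returns (events, costs) tables.

    Events: device_id, booked_at, started_at, finished_at, report_at,
    revenue — chronological per device, minute-precision timestamps,
    non-overlapping on each device.  Costs: one row per (device, month)
    with operating_cost, depreciation, energized_minutes; energized time is
    never less than the summed scan minutes of the month.
    """
    rng = np.random.default_rng(config.seed)
    months = _months(config)
    ev_rows: list[dict] = []
    cost_rows: list[dict] = []
    for dev, g in zip(config.device_ids, config.efficiency_multipliers):
        cursor = pd.Timestamp.min  # guards non-overlap across day/month edges
        for period in months:
            days = period.days_in_month
            month_start = period.to_timestamp()
            busy_minutes = 0.0
            for day in range(days):
                n_today = max(1, int(rng.poisson(config.mean_exams_per_day * g)))
                # faster scanner: shorter scans, same tariff
                dur = rng.normal(config.mean_exam_minutes / g,
                                 config.sd_exam_minutes / g, size=n_today)
                dur = np.clip(dur, _MIN_EXAM_MINUTES / g, None)
                dur = np.maximum(np.round(dur), 1.0)
                idle = np.round(rng.exponential(2.0, size=n_today))
                lead = np.maximum(np.round(rng.gamma(
                    config.appointment_lead_shape,
                    config.appointment_lead_mean / config.appointment_lead_shape / g,
                    size=n_today)), 1.0)
                delay = np.maximum(np.round(rng.gamma(
                    config.report_delay_shape,
                    config.report_delay_mean / config.report_delay_shape / g,
                    size=n_today)), 1.0)
                revenue = np.round(config.tariff_per_exam * rng.lognormal(
                    -config.revenue_sigma ** 2 / 2, config.revenue_sigma,
                    size=n_today), 2)
                t = max(month_start + pd.Timedelta(days=day, hours=8), cursor)
                for k in range(n_today):
                    start = t
                    finish = start + pd.Timedelta(minutes=float(dur[k]))
                    ev_rows.append({
                        "device_id": dev,
                        "booked_at": start - pd.Timedelta(minutes=float(lead[k])),
                        "started_at": start,
                        "finished_at": finish,
                        "report_at": finish + pd.Timedelta(minutes=float(delay[k])),
                        "revenue": float(revenue[k]),
                    })
                    busy_minutes += float(dur[k])
                    t = finish + pd.Timedelta(
                        minutes=config.prep_minutes + float(idle[k]))
                cursor = t
            energized = config.energized_minutes_per_day * days
            energized = max(energized, busy_minutes * 1.05)
            cost = config.operating_cost_base * rng.lognormal(
                -config.operating_cost_sigma ** 2 / 2, config.operating_cost_sigma)
            cost_rows.append({
                "device_id": dev,
                "month": str(period),
                "operating_cost": round(float(cost), 2),
                "depreciation": float(config.depreciation_per_month),
                "energized_minutes": round(float(energized), 1),
            })
    events = pd.DataFrame(ev_rows).sort_values(
        ["device_id", "started_at"]).reset_index(drop=True)
    costs = pd.DataFrame(cost_rows).sort_values(
        ["device_id", "month"]).reset_index(drop=True)
    return events, costs
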