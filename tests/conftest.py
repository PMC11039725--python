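import numpy as np
import pandas as pd
import pytest

from fleetdea import FleetConfig, build_panel, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> FleetConfig:
    """4 devices x 6 months, device A planted high-efficiency."""
    return FleetConfig(n_devices=4, n_months=6,
                       efficiency_multipliers=(1.3, 1.0, 0.95, 0.9), seed=42)


@pytest.fixture(scope="session")
def small_fleet(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_panel(small_fleet) -> pd.DataFrame:
    events, costs = small_fleet
    return build_panel(events, costs)


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Tiny hand-written event table; timestamps given as strings."""
    df = pd.DataFrame(rows)
    for col in ("booked_at", "started_at", "finished_at", "report_at"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_costs(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
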