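import warnings

import numpy as np
import pandas as pd
import pytest

from droughtmeta import SimConfig, calibrate_exposure_mix, simulate_panel

# stage-1 IRLS fits emit benign domain warnings on boundary alpha values
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def calibrated_config() -> SimConfig:
    """Config whose exposure mix matches the national county-month mix."""
    return calibrate_exposure_mix(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_panel(calibrated_config) -> pd.DataFrame:
    """12 counties x 120 months, labeled, with both outcomes."""
    cfg = calibrated_config.replace(n_counties=12, n_months=120, seed=42,
                                    population_median=60_000.0)
    return simulate_panel(cfg)


def make_county_frame(n: int, population: float = 50_000.0, seed: int = 0,
                      labels=None) -> pd.DataFrame:
    """Minimal single-county modeling frame with controllable labels."""
    rng = np.random.default_rng(seed)
    cal = (np.arange(n) % 12) + 1
    seasons = np.array(["DJF", "MAM", "JJA", "SON"], dtype=object)[(cal % 12) // 3]
    if labels is None:
        labels = np.array(["NONE"] * n, dtype=object)
    return pd.DataFrame({
        "county_id": "00001",
        "month_index": np.arange(1, n + 1),
        "month": cal,
        "season": seasons,
        "temperature": 12 + 10 * np.cos(2 * np.pi * (cal - 7) / 12) + rng.normal(0, 1, n),
        "population": population,
        "exposure_label": labels,
    })
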