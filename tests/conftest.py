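import numpy as np
import pandas as pd
import pytest

from aquatwin.series import CHANNELS, SensorSeries


def build_series(
    n: int = 10,
    cadence_min: int = 1,
    start: str = "2026-01-01",
    provenance: str = "raw",
    **channels,
) -> SensorSeries:
    """Small helper: SensorSeries with given channel arrays, rest defaulted."""
    idx = pd.date_range(start, periods=n, freq=f"{cadence_min}min", tz="UTC")
    data = {
        "DO": np.full(n, 6.0), "NH3": np.full(n, 0.2), "Temp": np.full(n, 27.0),
        "pH": np.full(n, 7.5), "Turb": np.full(n, 10.0),
        "Aaer": np.zeros(n), "Afeed": np.zeros(n),
        "P": np.full(n, 10.0), "E": np.cumsum(np.full(n, 10.0)) / 60.0,
    }
    for k, v in channels.items():
        data[k] = np.asarray(v, dtype=float)
    frame = pd.DataFrame({ch: data[ch] for ch in CHANNELS}, index=idx)
    return SensorSeries(frame, pd.Timedelta(minutes=cadence_min), provenance)


@pytest.fixture
def series_factory():
    return build_series


@pytest.fixture
def small_scenario():
    from aquatwin.scenario import ScenarioConfig

    return ScenarioConfig(duration_days=2, seed=7)
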