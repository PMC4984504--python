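import numpy as np
import pandas as pd
import pytest

from divetrace import (
    EnvironmentModel,
    SimulationConfig,
    TagSeries,
    annotate_excursions,
    detect_excursions,
    simulate_track,
)


def make_series(depths, interval_s=120.0, temps=None, individual_id="t", start="2012-05-01T00:00:00Z"):
    """TagSeries from a plain depth list (helper shared across tests)."""
    depths = np.asarray(depths, dtype=float)
    if temps is None:
        temps = 25.0 - depths / 100.0
    ts = pd.date_range(start, periods=len(depths), freq=f"{int(interval_s)}s", tz="UTC")
    frame = pd.DataFrame({"timestamp": ts, "depth": depths, "temperature": temps})
    return TagSeries(individual_id=individual_id, frame=frame, nominal_interval_s=interval_s)


@pytest.fixture(scope="session")
def default_sim():
    """Default study-condition simulation: 10 individuals x 30 days."""
    cfg = SimulationConfig(seed=20120501)
    series_list, truths = simulate_track(cfg, EnvironmentModel())
    return cfg, series_list, truths


@pytest.fixture(scope="session")
def detected(default_sim):
    """Detected + annotated excursions from the default simulation."""
    cfg, series_list, truths = default_sim
    env = EnvironmentModel()
    excs = []
    for s in series_list:
        excs.extend(detect_excursions(s))
    annotate_excursions(excs, cfg.lat, cfg.lon, oxygen=env)
    return excs
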