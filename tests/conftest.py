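import logging

import numpy as np
import pandas as pd
import pytest

from sealforage.config import SimConfig
from sealforage.synthetic import simulate_dataset

logging.getLogger("sealforage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic 3-animal, 30-day synthetic SRDL bundle."""
    cfg = SimConfig(n_animals=3, class_mix=(1 / 3, 1 / 3, 1 / 3),
                    duration_days=30.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def straight_track(n=50, speed_ms=1.0, dt_hr=1.0, lat=70.0, lon0=0.0,
                   animal="a", start="2008-04-01"):
    """Due-east constant-speed track (unprojected small-angle construction)."""
    from sealforage.geo import destination
    times = pd.date_range(start, periods=n, freq=pd.Timedelta(hours=dt_hr))
    step_km = speed_ms * 3.6 * dt_hr
    lons, lats = [lon0], [lat]
    for _ in range(n - 1):
        lo, la = destination(lons[-1], lats[-1], 90.0, step_km)
        lons.append(lo)
        lats.append(la)
    return pd.DataFrame({"animal_id": animal, "time": times,
                         "lon": lons, "lat": lats})


@pytest.fixture
def straight_track_factory():
    return straight_track
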