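import numpy as np
import pandas as pd
import pytest

from pengmove.simulate import SimConfig, simulate_dataset


def make_track(lonlats, start="2014-01-01", gap_hours=2.0, ind="A"):
    """Small helper: build a track frame from (lon, lat) pairs."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "id": ind,
            "timestamp": [t0 + pd.Timedelta(hours=gap_hours * i) for i in range(len(lonlats))],
            "lon": [p[0] for p in lonlats],
            "lat": [p[1] for p in lonlats],
        }
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    """Reduced study: fewer, shorter deployments; all structure retained."""
    return SimConfig(
        seed=42,
        n_juveniles=4,
        n_nonbreeders=2,
        duration_days_mean={"juvenile": 170.0, "nonbreeder": 170.0},
        duration_days_sd={"juvenile": 10.0, "nonbreeder": 10.0},
        transit_start_day=60.0,
        transit_duration_days=35.0,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg):
    tracks, dives, env, manifest = simulate_dataset(tiny_cfg)
    return {"tracks": tracks, "dives": dives, "env": env, "manifest": manifest}


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(20140101)
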