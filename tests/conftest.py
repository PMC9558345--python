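import numpy as np
import pandas as pd
import pytest

from pulsetrack import scenarios, synth


@pytest.fixture(scope="session")
def landscape():
    """Small (2 km) landscape shared by read-only tests."""
    return synth.generate_landscape(synth.LandscapeConfig(extent=2000.0, seed=7))


@pytest.fixture(scope="session")
def elk_sim(landscape):
    """Five parturient elk with truth events on the shared landscape."""
    cfg = scenarios.elk_prey_config()
    fixes, events = synth.simulate_prey(cfg, landscape, 5, seed=21, duration_d=60.0)
    return fixes, events


def make_fixes(xy, start="2021-05-01", interval_min=30, animal_id="a1", species="elk", sex="F"):
    """Fix table from a coordinate list at a regular interval."""
    xy = np.asarray(xy, dtype=float)
    t = pd.date_range(start, periods=len(xy), freq=pd.Timedelta(minutes=interval_min), tz="UTC")
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "species": species,
            "sex": sex,
            "t": t,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
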