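import numpy as np
import pandas as pd
import pytest

from ciliateco.core import AbundanceTable, EnvFrame, SampleFrame
from ciliateco.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic survey shared by read-only tests."""
    cfg = SimConfig(seed=11, n_stations_shelf=4, n_stations_basin=6,
                    n_taxa=25, n_phyto=12, n_coupled=4)
    return simulate(cfg)


@pytest.fixture()
def toy_table():
    data = pd.DataFrame(
        [[10.0, 0.0, 5.0],
         [0.0, 4.0, 4.0],
         [1.0, 1.0, 2.0],
         [3.0, 0.0, 0.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(data)


@pytest.fixture()
def toy_frame():
    data = pd.DataFrame({
        "station_id": ["st1", "st1", "st2", "st2"],
        "longitude": [113.5, 113.5, 120.0, 120.0],
        "latitude": [20.0, 20.0, 22.0, 22.0],
        "season": ["summer", "winter", "summer", "winter"],
        "sample_depth": [0.0, 50.0, 0.0, 500.0],
        "bottom_depth": [80.0, 80.0, 1200.0, 1200.0],
    }, index=["s1", "s2", "s3", "s4"])
    return SampleFrame(data)


@pytest.fixture()
def toy_env(toy_frame):
    rng = np.random.default_rng(5)
    cols = ["Tem", "Sal", "pH", "DO", "Nox", "SRP", "Si",
            "Chla", "MChla", "NChla", "PChla", "Syn", "Peuk", "Pro"]
    data = pd.DataFrame(rng.uniform(1, 10, size=(4, len(cols))),
                        index=toy_frame.samples, columns=cols)
    return EnvFrame(data)
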