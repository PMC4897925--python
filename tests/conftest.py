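import numpy as np
import pandas as pd
import pytest

from minetown import geodesy, synthetic


@pytest.fixture(scope="session")
def study_fixture():
    """Default synthetic study: 275 children, two mines, realistic NA gaps."""
    table, sources = synthetic.simulate_study(synthetic.TownConfig(seed=42))
    return table, sources


@pytest.fixture(scope="session")
def single_source():
    """One mine at a known location, for crafted-distance fixtures."""
    return pd.DataFrame({"source_id": ["gold"], "lat": [-30.30], "lon": [-71.10]})


def children_at_distances(distances_km, source_lat=-30.30, source_lon=-71.10):
    """Children placed due north of a source at exact great-circle distances."""
    distances_km = np.asarray(distances_km, dtype=float)
    lat = source_lat + distances_km / geodesy.KM_PER_DEG
    return pd.DataFrame({
        "child_id": [f"c{i:05d}" for i in range(len(distances_km))],
        "lat": lat,
        "lon": np.full(len(distances_km), source_lon),
    })
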