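import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import LineString

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture()
def toy_segments():
    """Three parallel 50 m segments, 100 m apart, in a metric plane."""
    return pd.DataFrame({
        "segment_id": ["A", "B", "C"],
        "city_id": ["T"] * 3,
        "geometry": [LineString([(0, 0), (50, 0)]),
                     LineString([(0, 100), (50, 100)]),
                     LineString([(0, 200), (50, 200)])],
        "length": [50.0] * 3,
    })


@pytest.fixture(scope="session")
def small_study():
    """One small combined-shift study shared by read-only tests."""
    from transferlur import make_study
    return make_study("both_shifts_tobler", seed=7, n_segments_source=400,
                      n_segments_target=400, include_target_campaign=False)
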