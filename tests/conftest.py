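import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tidalcarbon.synthetic import SynthConfig, generate_gauges, generate_inventory, generate_sites

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def sites(default_config):
    """One default synthetic site network (350 sites, 7 regions)."""
    return generate_sites(default_config)


@pytest.fixture(scope="session")
def inventory(default_config):
    return generate_inventory(default_config)


@pytest.fixture(scope="session")
def gauges(default_config):
    return generate_gauges(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_sites_frame(lats, lons, cars, regions=None, **extra):
    """Minimal hand-built site table for upscaling tests."""
    n = len(lats)
    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "source_id": extra.pop("source_id", ["src0"] * n),
            "lat": lats,
            "lon": lons,
            "region": regions if regions is not None else ["Mid Atlantic"] * n,
            "car_gC_m2_yr": cars,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
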