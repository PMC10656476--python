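import numpy as np
import pytest

from citypop import SynthConfig, make_baseline, make_geo


@pytest.fixture(scope="session")
def small_world():
    """3 provinces x 3 cities, 20M people, fixed seed — shared, read-only."""
    cfg = SynthConfig(
        n_provinces=3, cities_per_province=3, total_population=20e6, seed=11
    )
    geo = make_geo(cfg)
    state, rates = make_baseline(cfg, geo)
    return cfg, geo, state, rates


@pytest.fixture(scope="session")
def medium_world():
    """5 provinces x 4 cities, 50M people — the default synthetic system."""
    cfg = SynthConfig(seed=7)
    geo = make_geo(cfg)
    state, rates = make_baseline(cfg, geo)
    return cfg, geo, state, rates


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
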