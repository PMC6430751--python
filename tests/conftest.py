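import numpy as np
import pandas as pd
import pytest

import biogapfill as bg


@pytest.fixture(scope="session")
def harvest36():
    """Complete 36-culture harvest table at default study conditions."""
    return bg.generate_harvest_table(bg.GeneratorConfig(seed=1, n_cultures=36))


@pytest.fixture(scope="session")
def harvest90():
    return bg.generate_harvest_table(bg.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_ts():
    """Small noiseless time series: four log trends and one constant."""
    specs = {
        p: bg.TrendSpec("logarithmic", a=1 + 0.3 * i, b=1.0, c=1.0, d=float(i))
        for i, p in enumerate("ABCD")
    }
    specs["E"] = bg.TrendSpec("constant", d=5.0)
    cfg = bg.GeneratorConfig(n_cultures=20, trend_specs=specs, seed=4)
    return bg.generate_time_series(cfg)


@pytest.fixture(scope="session")
def default_ts():
    """Default 75-culture, 14-parameter, 14-day time series with noise."""
    return bg.generate_time_series(bg.GeneratorConfig(n_cultures=75, seed=2))


@pytest.fixture(scope="session")
def shared_trend_ts():
    """Fixture with a known grouping: F, H, J share one log trend (distinct
    offsets); A is an S-shaped cubic; M a falling log; E a rising steep log."""
    specs = {}
    for p in ("F", "H", "J"):
        specs[p] = bg.TrendSpec(
            "logarithmic", a=2.0, b=1.0, c=1.0, d=float(ord(p)), noise_sd=0.01, offset_sd=0.01
        )
    specs["A"] = bg.TrendSpec("cubic", a=0.02, b=-0.4, c=2.0, d=1.0, noise_sd=0.01)
    specs["M"] = bg.TrendSpec("logarithmic", a=-3.0, b=1.0, c=1.0, d=50.0, noise_sd=0.01)
    specs["E"] = bg.TrendSpec("cubic", a=0.0, b=-1.0, c=13.0, d=3.0, noise_sd=0.01)
    return bg.generate_time_series(bg.GeneratorConfig(n_cultures=10, trend_specs=specs, seed=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
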