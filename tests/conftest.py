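import warnings

import numpy as np
import pytest

from coralacclim import (
    GlobalParams,
    RunSettings,
    ScenarioSpec,
    region_preset,
    spin_up,
    synthetic_forcing,
)

REGION_NAMES = ("GBR", "SEA", "CAR")


@pytest.fixture(scope="session")
def params():
    return GlobalParams()


@pytest.fixture(params=REGION_NAMES, scope="session")
def region(request):
    return region_preset(request.param)


@pytest.fixture(scope="session")
def gbr():
    return region_preset("GBR")


@pytest.fixture(scope="session")
def spun_up_states(params):
    """Published-protocol spin-up end state per region (trait still drifting,
    hence the suppressed warning)."""
    out = {}
    for name in REGION_NAMES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = spin_up(region_preset(name), params, RunSettings())
    return out


@pytest.fixture(scope="session")
def historical_forcing():
    """Synthetic 1955-2010 GBR-like record: mild warming, seasonal cycle, noise."""
    reg = region_preset("GBR")
    return synthetic_forcing(
        ScenarioSpec(
            baseline_mean=reg.spinup_T,
            target_rise=0.6,
            seed=101,
            span=(1955, 2010),
            label="synthetic historical",
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
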