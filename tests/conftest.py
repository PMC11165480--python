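import numpy as np
import pandas as pd
import pytest

import phoskin as pk


@pytest.fixture(scope="session")
def panel():
    return pk.bt4131_panel()


@pytest.fixture(scope="session")
def ratios(panel):
    return pk.default_ratio_table(panel)


@pytest.fixture(scope="session")
def base_draw():
    """One fixed parameter draw shared by pathway-level tests."""
    spec = pk.SamplingSpec(seed=7, n_draws=1)
    return pk.sample_parameters(spec, 0)


@pytest.fixture(scope="session")
def wt_params(ratios, base_draw):
    return pk.build_variant_params(ratios, base_draw, "WT")


def make_params(**overrides):
    """A hand-set, well-conditioned parameter set for unit tests."""
    defaults = dict(
        vmax=np.full(12, 0.8),
        km=np.full(12, 1.0),
        reg_basal=np.full(4, 0.4),
        reg_n=np.full(4, 2.0),
        reg_ka=np.full(4, 0.5),
        ki=0.5,
        transport_n=2.0,
    )
    defaults.update(overrides)
    return pk.PathwayParameters(**defaults)


@pytest.fixture
def simple_params():
    return make_params()
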