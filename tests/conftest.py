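import numpy as np
import pytest

import neuroemu as ne


@pytest.fixture(scope="session")
def space31():
    return ne.default_parameter_space(31)


@pytest.fixture(scope="session")
def stable_params(space31):
    """A subthreshold-stable reference individual (no spikes under IVf_3)."""
    return ne.reference_params(space31)


@pytest.fixture(scope="session")
def small_dataset(space31):
    """400 random individuals with features from the weak protocol only.

    Shared across emulation/missingness tests to keep the suite fast; the
    steady-state voltage is smooth over most of the box while the spike
    features carry structural missingness.
    """
    params, table, space = ne.make_dataset(
        400, d=31, seed=101, protocols=[ne.IVF_3], dt=0.2, space=space31
    )
    return params, table, space


@pytest.fixture(scope="session")
def idrest_dataset(space31):
    """300 individuals under the strong protocol: rich missingness structure."""
    params, table, space = ne.make_dataset(
        300, d=31, seed=202, protocols=[ne.IDREST_7], dt=0.2, space=space31
    )
    return params, table, space


@pytest.fixture
def rng():
    return np.random.default_rng(42)
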