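import numpy as np
import pytest

from ampar_trafficking import (TraffickingParams, default_fit, coop_k_UB0,
                               experiments)


@pytest.fixture(scope="session")
def base_params():
    return TraffickingParams()


@pytest.fixture(scope="session")
def mf_fit():
    """Packaged mean-field calibration fixture."""
    return default_fit()


@pytest.fixture(scope="session")
def coop_params(base_params, mf_fit):
    """Basal parameters with the cooperative fixed-point binding rate."""
    return base_params.replace(k_UB0=coop_k_UB0(base_params, mf_fit),
                               k_endo=base_params.k_endo)


@pytest.fixture(scope="session")
def eltp_tables(mf_fit):
    """One shared run of the four-model E-LTP comparison (dt=0.5 s)."""
    curves, diag = experiments.experiment_eltp_comparison(
        fit=mf_fit, t_end=7200.0, dt=0.5)
    return curves, diag


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
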