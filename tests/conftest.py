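import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alpsim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tinnitus_params():
    return alpsim.tinnitus_group_params()


@pytest.fixture(scope="session")
def hc_params():
    return alpsim.control_group_params()


@pytest.fixture(scope="session")
def coupling():
    return alpsim.CouplingSpec()


@pytest.fixture(scope="session")
def geometry():
    return alpsim.PhantomGeometry()


@pytest.fixture(scope="session")
def gtab():
    return alpsim.default_gradient_table()


def degenerate_params(params, cognitive_too=False):
    """Copy of a GroupParams with all (diffusivity, optionally score) SDs 0."""
    from dataclasses import replace

    kw = {"diffusivity_sd": {k: 0.0 for k in params.diffusivity_sd}}
    if cognitive_too:
        kw["score_sd"] = {k: 0.0 * v for k, v in params.score_sd.items()}
    return replace(params, **kw)


@pytest.fixture(scope="session")
def tinnitus_degenerate(tinnitus_params):
    return degenerate_params(tinnitus_params)
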