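"""Shared fixtures: the bundled WTsim profile, its steady state and a
simulated mitochondrial stress test (session-scoped; simulations are reused
across tests)."""

import numpy as np
import pytest

from mitoflux import population as pop
from mitoflux import rc_model as rc


@pytest.fixture(scope="session")
def wtsim():
    params, init = rc.load_profile("WTsim")
    return params, init


@pytest.fixture(scope="session")
def params(wtsim):
    return wtsim[0]


@pytest.fixture(scope="session")
def init_state(wtsim):
    return wtsim[1]


@pytest.fixture(scope="session")
def steady(params, init_state):
    return rc.find_steady_state(params, init_state)


@pytest.fixture(scope="session")
def stress_tc(params, init_state):
    """WTsim mitochondrial stress test trajectory (tight tolerances)."""
    return pop.run_stress_test(params, init_state, rtol=1e-8, grid_dt=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_valid_state(rng, params) -> rc.ModelState:
    """A random state inside all pool and positivity bounds."""
    return rc.ModelState(
        dpsi=float(rng.uniform(-30, 190)),
        NADH_x=float(rng.uniform(0.02, 0.98) * params.NADtot),
        QH2=float(rng.uniform(0.02, 0.98) * params.Qtot),
        Cred=float(rng.uniform(0.02, 0.98) * params.Ctot),
        ATP_x=float(rng.uniform(1e-5, 8e-3)),
        ADP_x=float(rng.uniform(1e-4, 1e-2)),
        Pi_x=float(rng.uniform(1e-4, 1e-2)),
        ATP_i=float(rng.uniform(1e-5, 4e-3)),
        ADP_i=float(rng.uniform(1e-5, 2e-3)),
        Pi_i=float(rng.uniform(1e-4, 5e-3)),
        ATP_c=float(rng.uniform(1e-5, 4e-3)),
        ADP_c=float(rng.uniform(1e-5, 2e-3)),
        Pi_c=float(rng.uniform(1e-4, 5e-3)),
        H_x=float(10 ** -rng.uniform(6.8, 8.0)),
        K_x=float(rng.uniform(0.02, 0.2)),
        Mg_x=float(rng.uniform(1e-4, 1e-3)),
    )
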