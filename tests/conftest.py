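import numpy as np
import pytest

import lamella as lm


@pytest.fixture(scope="session")
def params() -> lm.ModelParameters:
    return lm.load_parameters()


@pytest.fixture(scope="session")
def controls() -> lm.NumericalControls:
    return lm.NumericalControls()


@pytest.fixture(scope="session")
def baseline(params) -> lm.SteadyStateSolution:
    """Converged confined baseline solve (shared across tests)."""
    return lm.solve_steady_state(params, mode="confined")


@pytest.fixture(scope="session")
def edge15(params) -> lm.EdgeState:
    """Edge state at the physiological leading-edge monomer concentration."""
    return lm.make_edge_state(15.0, params)


@pytest.fixture(scope="session")
def traj_baseline(params, controls) -> lm.SubunitStateTrajectory:
    edge = lm.make_edge_state(15.0, params)
    t_end = controls.resolved_t_uc_max(params) + params.L_sys / edge.V + 1.0
    return lm.subunit_trajectory(params, t_end, controls.dt)


@pytest.fixture(scope="session")
def unconfined_no_tm(params) -> lm.SteadyStateSolution:
    """Unconfined solve with tropomyosin disabled at the reference D."""
    return lm.solve_steady_state(params.replace(r_tm=0.0), mode="unconfined")
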