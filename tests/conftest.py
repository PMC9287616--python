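import numpy as np
import pytest

import tnbcqsp as q


@pytest.fixture(scope="session")
def default_params():
    return q.default_parameters()


@pytest.fixture(scope="session")
def full_system():
    """The assembled default model (kernel compiled once per session)."""
    return q.assemble_model()


@pytest.fixture(scope="session")
def baseline_trajectory(full_system):
    """Untreated 400-day course from one seed cancer cell."""
    return q.simulate(full_system, (0.0, 400.0), record_grid=1.0)


def rhs_at(system, overrides, t=0.0):
    """Evaluate the model derivative at a state built from name->value
    overrides (all other states zero); returns a name->derivative dict."""
    y = np.zeros(system.n_odes)
    for name, value in overrides.items():
        y[system.state_index[name]] = value
    dy = system.rhs(t, y, np.zeros_like(y))
    return {name: dy[i] for name, i in system.state_index.items()}


@pytest.fixture(scope="session")
def derivative_probe():
    return rhs_at
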