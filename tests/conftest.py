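import copy

import numpy as np
import pytest

from vegfpkpd import build_model, load_parameter_set, solve_steady_state
from vegfpkpd.calibration import fit_rates


@pytest.fixture(scope="session")
def params():
    return load_parameter_set()


@pytest.fixture(scope="session")
def model(params):
    return build_model(params)


@pytest.fixture(scope="session")
def baseline_ss(model):
    """Steady state at the shipped (uncalibrated) secretion rates."""
    return solve_steady_state(model)


@pytest.fixture(scope="session")
def calibrated(params):
    """Calibrated baseline: model fitted to the Table-4 targets.

    Session-scoped: the fit is the single most expensive computation in the
    suite and everything downstream (summaries, sweeps, acceptance checks)
    reuses it.
    """
    m = build_model(params)
    fit = fit_rates(m)
    return m, fit


@pytest.fixture()
def raw_config(params):
    return copy.deepcopy(params.raw_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
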