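import numpy as np
import pytest

from ferment_dfba import toy
from ferment_dfba.engine import DfbaProblem, SolverOptions


@pytest.fixture(scope="session")
def toy_model():
    return toy.build_toy_model()


@pytest.fixture(scope="session")
def standard_preset():
    return toy.get_preset("standard_25C")


@pytest.fixture(scope="session")
def cold_preset():
    return toy.get_preset("cold_12C")


@pytest.fixture(scope="session")
def standard_traj(standard_preset):
    """Accurate trajectory (with fluxes) for the 25 degC scenario."""
    return DfbaProblem.from_preset(standard_preset).simulate(SolverOptions())


@pytest.fixture(scope="session")
def cold_traj(cold_preset):
    """Accurate trajectory (with fluxes) for the 12 degC scenario."""
    return DfbaProblem.from_preset(cold_preset).simulate(SolverOptions())


@pytest.fixture(scope="session")
def cold_fast_traj(cold_preset):
    """Fast-mode trajectory used as a cheap simulation ground truth."""
    return DfbaProblem.from_preset(cold_preset).simulate(
        SolverOptions.fast_preset())


@pytest.fixture(scope="session")
def noisy_cold_dataset(cold_preset, cold_traj):
    df, _ = toy.generate_dataset(cold_preset, noise_cv=0.05, seed=7,
                                 trajectory=cold_traj)
    return df
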