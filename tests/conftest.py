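import numpy as np
import pytest

from nbgam.inference import build_design_matrices
from nbgam.io_design import parse_design
from nbgam.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_scenario1():
    """A small nonlinear-effect dataset shared across tests."""
    cfg = SimulationConfig(scenario="I", n_genes=120, m=30, a=3.0,
                           de_fraction=0.05, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def smooth_design(small_scenario1):
    """Design matrices for s(x) on the shared dataset's covariate."""
    cd = small_scenario1.coldata()
    return build_design_matrices(parse_design("s(x)", cd), cd)
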