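import numpy as np
import pytest

import pmfgrn as pg


@pytest.fixture(scope="session")
def tiny_data():
    """Small synthetic dataset shared by fast tests."""
    cfg = pg.SimulationConfig(n_cells=40, n_genes=30, n_tfs=3,
                              edge_density=0.25, seed=5)
    return pg.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_state():
    """A perturbed 4-cell / 3-gene / 2-TF variational state."""
    r = np.random.default_rng(42)
    cfg = pg.HyperparameterConfig()
    prior_logits = r.normal(size=(3, 2))
    state = pg.init_state(4, prior_logits, cfg)
    state.U_mean = state.U_mean + 0.3 * r.standard_normal((4, 2))
    state.A_mean = state.A_mean + 0.2 * r.standard_normal((3, 2))
    state.B_mean = state.B_mean + 0.1 * r.standard_normal((3, 2))
    return state, prior_logits, cfg
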