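import numpy as np
import pytest

import cytocausal as cc


@pytest.fixture(scope="session")
def chain_model():
    """A -> P1 -> P2 with a third isolated marker."""
    return cc.make_chain_model(p=3, chain_coef=0.8, activator_effect=1.0)


@pytest.fixture(scope="session")
def chain_bundle(chain_model):
    """27 dose-zero replicate plates, n=500 cells per condition."""
    design = cc.make_study_design(
        chain_model, n_inhibitors=27, n_dosages=1, n_per_condition=500, seed=11
    )
    return cc.simulate_study(chain_model, design, seed=13)


@pytest.fixture(scope="session")
def acyclic3_model():
    """Fully connected 3-marker acyclic model with known coefficients."""
    B = np.array([[0.0, 0.0, 0.0], [0.6, 0.0, 0.0], [0.3, 0.5, 0.0]])
    return cc.CausalModel(
        B=B, Sigma_eps=np.eye(3), a=np.array([1.0, 0.0, 0.0]), labels=("x", "y", "z")
    )
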