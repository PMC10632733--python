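import numpy as np
import pytest

from mranet.data import ResponseDataset
from mranet.model import MRAModel
from mranet.scenarios import chain_scenario


@pytest.fixture(scope="session")
def chain():
    return chain_scenario()


@pytest.fixture(scope="session")
def chain_noiseless(chain):
    """Noise-free dataset from the chain scenario's ground truth."""
    from mranet.scenarios import generate_dataset

    return generate_dataset(chain.structure, chain.perturbation_map,
                            chain.true_params["XX"], design=chain.design,
                            readouts=chain.readouts, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def chain_fit(chain):
    """A converged fit on one noisy chain dataset (shared across tests)."""
    ds = chain.datasets(seed=101, attach_true_sigma=True)["XX"]
    model = MRAModel(chain.structure, chain.perturbation_map, ds)
    return model.fit(n_starts=15, seed=7)


def two_node_model(r_value=0.5, inhibitor_strength=-2.0):
    """Minimal A->B model with one inhibitor on A; returns (model, params)."""
    from mranet.structure import NetworkStructure, PerturbationMap

    s = NetworkStructure(("A", "B"), (("A", "B"),), {"A": "enzyme", "B": "enzyme"})
    p = PerturbationMap({"iA": ("A", "inhibition")})
    ds = ResponseDataset([(), ("iA",)], ["A", "B"], np.ones((2, 2, 1)))
    return MRAModel(s, p, ds), np.array([r_value, inhibitor_strength])
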