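import numpy as np
import pytest
from hypothesis import settings

import grnvae as g

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_default():
    """The default simulated dataset (600 cells, 200 genes, 15 TFs, 3 clusters)."""
    return g.simulate(g.SimulationConfig())


@pytest.fixture(scope="session")
def aligned_default(sim_default):
    data = g.filter_and_align(sim_default.expression, sim_default.prior)
    return g.split_train_val(data, 0.15, seed=0)


@pytest.fixture(scope="session")
def model_default(aligned_default):
    """A model trained for 100 epochs on the default simulation."""
    model, _ = g.train(aligned_default, g.ModelConfig(epochs=100, seed=0))
    return model


@pytest.fixture()
def tiny_prior():
    """2 TFs x 3 genes signed prior: A->g1(+), A->g2(-), B->g1(+)."""
    import scipy.sparse as sp

    return g.PriorGRN(
        np.array(["A", "B"], dtype=object),
        np.array(["g1", "g2", "g3"], dtype=object),
        sp.csr_matrix(np.array([[1.0, -1.0, 0.0], [1.0, 0.0, 0.0]])),
    )
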