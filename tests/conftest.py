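import numpy as np
import pytest

from cads import cads_model, synthdata


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by model-level tests."""
    return synthdata.simulate(n_cells=12, n_genes=30, k_causal=4, n_drugs=8,
                              n_examples=300, noise_sd=0.1, confound_rho=0.3,
                              seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    return cads_model.TrainConfig(epochs=3, batch_size=64, hidden=(32, 16),
                                  d_model=16, d_g=8, seed=11,
                                  mask_finetune_epochs=10, mask_refine_reps=2)


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset, tiny_config):
    """A briefly trained model — enough for API-level checks."""
    return cads_model.train(tiny_dataset, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
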