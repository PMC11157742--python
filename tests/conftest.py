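import numpy as np
import pytest

from omicsfuse import (ModalitySim, MultiOmicsVAE, SimConfig, attach_survival,
                       simulate_multiomics)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small two-modality dataset with survival outcomes and clear subtype
    structure, shared read-only across tests."""
    cfg = SimConfig(
        n_samples=300, n_subtypes=2, latent_dim_true=8,
        modalities=[ModalitySim("rna", 60, noise_sd=0.05),
                    ModalitySim("meth", 50, noise_sd=0.05)],
        subtype_shift=2.0, censor_rate=0.3, seed=11)
    dataset, truth = simulate_multiomics(cfg)
    dataset = attach_survival(dataset, truth, cfg.censor_rate, seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def pretrained(sim_dataset):
    """A briefly pretrained backbone.  Tests that fine-tune with a
    non-frozen backbone must deepcopy it first."""
    dataset, _ = sim_dataset
    vae = MultiOmicsVAE(latent_dim=8, hidden_dim=32, disc_hidden=32,
                        max_epochs=12, seed=5)
    return vae.fit(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
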