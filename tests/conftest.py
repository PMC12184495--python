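import numpy as np
import pytest

from eigensteer import eigengenes, syndata


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted two-cluster expression dataset shared across tests."""
    cfg = syndata.SynthConfig(
        n_genes=120, n_baseline=40, n_variant=40, latent_rank=6, n_causal=1,
        noise_sd=0.5, seed=42,
    )
    expr, truth = syndata.generate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def small_basis(small_dataset):
    _, expr, _ = small_dataset
    return eigengenes.compute_basis(expr.values)


@pytest.fixture(scope="session")
def steering():
    return syndata.generate_steering_instances(
        n_dims=6, n_baseline=10, n_variant=10, n_perturbations=16, seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
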