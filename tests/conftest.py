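import numpy as np
import pytest

from scdmac import ScDMACConfig, SimulationConfig, simulate
from scdmac.masked_ae import MaskedAEConfig, MaskLossWeights
from scdmac.zinb import DenoiserConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def fast_fit_config(seed: int = 0, **overrides) -> ScDMACConfig:
    """A small-budget pipeline config for unit tests on tiny matrices."""
    cfg = ScDMACConfig(
        n_top_genes=2000,
        denoiser=DenoiserConfig(hidden_sizes=(64,), latent_dim=16, epochs=40,
                                patience=10, seed=seed),
        masked_ae=MaskedAEConfig(hidden_sizes=(64,), latent_dim=16, epochs=80,
                                 seed=seed),
        joint_epochs=20,
        refresh_interval=5,
        kmeans_restarts=5,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture
def tiny_sim():
    """Small, well-separated 3-cluster simulation for fast pipeline tests."""
    cfg = SimulationConfig(n_cells=150, n_genes=60, n_clusters=3,
                           log_fc=1.5, seed=7)
    X, labels, mu, pi = simulate(cfg)
    return X, labels, mu, pi
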