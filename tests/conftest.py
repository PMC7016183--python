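import numpy as np
import pytest

from modlight.autoencoder import AEArchitecture, AEModel, init_model
from modlight.expression import ExpressionMatrix
from modlight.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """4 genes × 3 samples with values spanning [0, 1]."""
    values = np.array([
        [0.0, 0.5, 1.0],
        [0.2, 0.4, 0.6],
        [0.9, 0.1, 0.3],
        [0.7, 0.8, 0.05],
    ])
    return ExpressionMatrix([f"g{i}" for i in range(4)], ["s0", "s1", "s2"], values)


@pytest.fixture(scope="session")
def small_compendium():
    """Reduced planted-module compendium shared across tests (read-only)."""
    cfg = SyntheticConfig(
        n_genes=300, n_samples=120, n_modules=4, genes_per_module=50,
        n_cell_types=2, n_diseases=2, seed=7,
    )
    return generate(cfg)


def random_model(n_genes: int, widths: tuple[int, ...], seed: int) -> AEModel:
    """Small dense model with random weights AND biases (init has zero biases)."""
    model = init_model(AEArchitecture(n_features=n_genes, hidden_widths=widths), seed)
    rng = np.random.default_rng(seed + 999)
    for W, b in zip(model.weights, model.biases):
        W += rng.normal(0, 0.5, size=W.shape)
        b += rng.normal(0, 0.5, size=b.shape)
    return model
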