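import numpy as np
import pandas as pd
import pytest

from palnn.genotypes import GenotypeMatrix, generate_genotypes
from palnn.nnmodel import ModelConfig, TrainedModel, train


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """200 individuals x 120 positions with block LD."""
    return generate_genotypes(200, 120, block_size=10, haplotype_pool=6, seed=7)


@pytest.fixture(scope="session")
def ld_genotypes() -> GenotypeMatrix:
    """Larger seeded matrix for LD statistics (2000 x 1000)."""
    return generate_genotypes(2000, 1000, block_size=10, haplotype_pool=8, seed=1)


def make_genotypes(values: np.ndarray, chrom=None, bp=None) -> GenotypeMatrix:
    """Wrap a raw ternary array in a GenotypeMatrix with default metadata."""
    values = np.asarray(values)
    n, L = values.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * L,
            "bp": bp if bp is not None else np.arange(1, L + 1) * 1000,
            "id": [f"v{j}" for j in range(L)],
        }
    )
    return GenotypeMatrix(
        values=values, variants=variants, sample_ids=[f"s{i}" for i in range(n)]
    )


@pytest.fixture(scope="session")
def tiny_trained_model():
    """Deterministic MLP fit on a single-SNP separable toy problem."""
    rng = np.random.default_rng(0)
    x = rng.choice([-1.0, 0.0, 1.0], size=(300, 20)).astype(np.float64)
    y = (x[:, 4] > 0).astype(int)
    cfg = ModelConfig(
        input_size=20, hidden1=12, hidden2=6, input_mask_p=0.0,
        hidden_dropout_p=0.0, learning_rate=1e-2, weight_decay=0.0,
        epochs=40, batch_size=64, label_noise_sd=0.0, input_noise_sd=0.0,
        n_val_cases=15, n_val_controls=15, seed=3, dtype="float64",
    )
    model = train(TrainedModel(cfg), x, y)
    return model, x, y
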