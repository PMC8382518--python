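import numpy as np
import pytest

from g3cs import ExpressionDataset, SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_dataset():
    """2 genes x 3 samples with known covariance [[1,-1],[-1,1]]."""
    return ExpressionDataset(
        np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
        ["g1", "g2"],
        ["s1", "s2", "s3"],
    )


@pytest.fixture
def random_dataset():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 8))
    return ExpressionDataset(
        X, [f"g{i}" for i in range(10)], [f"s{j}" for j in range(8)]
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """The default planted-structure dataset (200 genes x 60 samples)."""
    return generate_dataset(SyntheticSpec(seed=0))
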