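import numpy as np
import pytest

from shifttyper import synthetic


@pytest.fixture(scope="session")
def separated_model():
    """Class model with tiny within-class spread: near-perfect separability."""
    return synthetic.default_class_model(sd_scale=0.05)


@pytest.fixture(scope="session")
def default_model():
    return synthetic.default_class_model()


@pytest.fixture(scope="session")
def separated_protein(separated_model):
    return synthetic.sample_protein(separated_model, length=300, seed=42)


@pytest.fixture(scope="session")
def training_spins(separated_protein):
    _, spins = separated_protein
    return spins


def random_instance(rng, n_classes=None, n_features=None, n_per_class=None):
    """A random small LDA problem: returns (means, cov, counts, X, y)."""
    n_classes = n_classes or rng.integers(2, 6)
    n_features = n_features or rng.integers(1, 5)
    n_per_class = n_per_class or rng.integers(10, 51)
    means = rng.normal(0, 3, size=(n_classes, n_features))
    A = rng.normal(0, 1, size=(n_features, n_features))
    cov = A @ A.T + np.eye(n_features)
    X, y = [], []
    for k in range(n_classes):
        X.append(rng.multivariate_normal(means[k], cov, size=n_per_class))
        y.extend([k] * n_per_class)
    return means, cov, np.vstack(X), np.array(y)
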