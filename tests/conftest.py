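import numpy as np
import pytest

from nosecam.models import CnnConfig
from nosecam.preprocess import assemble_normalize, extract_baseline_features
from nosecam.sensor_sim import (
    MoleculeSpec,
    default_affinity_model,
    generate_dataset,
)


@pytest.fixture(scope="session")
def noiseless_model():
    return default_affinity_model(noise_sigma=0.0)


@pytest.fixture(scope="session")
def default_model():
    return default_affinity_model()


@pytest.fixture(scope="session")
def dataset42():
    """The default study dataset: 5 samples per category, seed 42."""
    samples, manifest = generate_dataset(5, seed=42)
    return samples, manifest


@pytest.fixture(scope="session")
def tensors42(dataset42):
    samples, _ = dataset42
    return [assemble_normalize(s) for s in samples]


@pytest.fixture(scope="session")
def features42(dataset42):
    samples, _ = dataset42
    return [extract_baseline_features(s) for s in samples]


@pytest.fixture
def ester_molecule():
    return MoleculeSpec("ethyl_acetate_like", "esters", 2, True, False)


@pytest.fixture
def fast_cnn_config():
    """Small epoch budget for unit tests that only need a trained model."""
    return CnnConfig(epochs=10, seed=7)


def tiny_two_class_problem(n_per_class=8, seed=3, sep=2.0, noise=0.05):
    """Two well-separated synthetic classes on the 40 x 14 x 3 grid.

    Class 'b' carries an extra bump on channel 3; both classes share a
    smooth background.  Returns (tensors, labels).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 40)
    base = np.exp(-((t - 0.4) ** 2) / 0.1)
    xs, ys = [], []
    for label in ("a", "b"):
        for _ in range(n_per_class):
            x = np.tile(base[:, None, None], (1, 14, 3)) * rng.uniform(0.8, 1.2)
            if label == "b":
                x[:, 2, :] += sep * np.exp(-((t - 0.7) ** 2) / 0.02)[:, None]
            x += rng.normal(0, noise, x.shape)
            xs.append(x)
            ys.append(label)
    return xs, ys
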