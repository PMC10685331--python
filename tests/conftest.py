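import warnings

import numpy as np
import pytest

from jointomics.data import ModalitySpec, MultiOmicsDataset, make_split
from jointomics.models import NetworkConfig, train
from jointomics.synthetic import generate, preset_config

warnings.filterwarnings("ignore", message=".*did not fully converge.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gaussian_pair():
    """300-sample two-modality gaussian dataset with labels and split."""
    cfg = preset_config("gaussian-pair", n_samples=300, seed=42)
    dataset, truth = generate(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def toy_specs():
    return [ModalitySpec("a", 10, "gaussian"), ModalitySpec("b", 10, "negbin")]


@pytest.fixture(scope="session")
def toy_batch(toy_specs):
    r = np.random.default_rng(7)
    Xa = r.normal(size=(6, 10))
    Xb = r.poisson(3.0, size=(6, 10)).astype(float)
    return [Xa, Xb]


@pytest.fixture(scope="session")
def tiny_trained_models(small_gaussian_pair):
    """One briefly trained model per flavor on the small gaussian pair."""
    dataset, _ = small_gaussian_pair
    cfg = NetworkConfig(latent_dim=8, hidden_layers=[16], max_epochs=8,
                        early_stopping_patience=8, seed=5)
    return {flavor: train(flavor, dataset, cfg)
            for flavor in ("ccvae", "cgvae", "poe", "moe", "refvae")}


def two_modality_dataset(n=60, d1=5, d2=4, seed=0, with_labels=True):
    """Small handmade gaussian dataset helper."""
    r = np.random.default_rng(seed)
    z = r.normal(size=(n, 2))
    X1 = z @ r.normal(size=(2, d1)) + 0.1 * r.normal(size=(n, d1))
    X2 = z @ r.normal(size=(2, d2)) + 0.1 * r.normal(size=(n, d2))
    labels = (z[:, 0] > 0).astype(int) if with_labels else None
    split = make_split(labels, n, (0.6, 0.2, 0.2), seed=seed).assignment
    return MultiOmicsDataset(
        modalities=[(ModalitySpec("m1", d1, "gaussian"), X1),
                    (ModalitySpec("m2", d2, "gaussian"), X2)],
        labels=labels, split=split,
    )
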