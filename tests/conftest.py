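import logging

import numpy as np
import pytest

from salqsar.data import chronological_split
from salqsar.gcnn import GCNNConfig, GraphConvClassifier, _init_params
from salqsar.synth import GeneratorSpec, generate_dataset

logging.getLogger("salqsar").setLevel(logging.WARNING)

# Small molecules (<= 12 heavy atoms) for exhaustive graph-oracle checks.
TINY_MOLECULES = [
    "C",
    "CC",
    "CCO",
    "CCCCC",
    "c1ccccc1",
    "c1ccncc1",
    "CC(=O)N",
    "C1CC1",
    "C1CCNCC1",
    "CC(C)CC(=O)O",
    "c1ccc2ccccc2c1",
    "CC.O",  # disconnected fragments
]


@pytest.fixture(scope="session")
def tiny_molecules():
    return list(TINY_MOLECULES)


@pytest.fixture(scope="session")
def random_model():
    """Classifier with random (untrained) weights, for architecture checks."""
    model = GraphConvClassifier(conv_sizes=(36, 50, 16))
    model.params_ = _init_params(model.config, np.random.default_rng(42))
    model.classes_ = np.array([0, 1])
    model.history_ = []
    return model


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-motif dataset small enough for quick training."""
    return generate_dataset(GeneratorSpec(n=200, seed=11))


@pytest.fixture(scope="session")
def trained_tiny_model(small_dataset):
    """A quickly trained model with real (non-random) saliency structure."""
    split = chronological_split(small_dataset)
    train = small_dataset.subset(list(split.final_train_ids))
    model = GraphConvClassifier.from_config(
        GCNNConfig(conv_sizes=(16, 16, 16), epochs=15, seed=5)
    )
    model.fit(train.df["smiles"].tolist(), train.df["label"].to_numpy())
    return model, split
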