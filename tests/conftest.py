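import numpy as np
import pytest

from retinacoach.contrastive import TrainConfig, train
from retinacoach.imaging import synth_fundus
from retinacoach.taxonomy import default_taxonomy

DESK_CLASSES = ["C0", "C14", "C11"]  # normal / bright drusen / dark wedge


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def desk_dataset():
    """120 synthetic single-label images of three visually distinct classes."""
    return [
        (synth_fundus({DESK_CLASSES[i % 3]}, size=64, seed=100 + i),
         {DESK_CLASSES[i % 3]})
        for i in range(120)
    ]


@pytest.fixture(scope="session")
def desk_test_set():
    return [
        (synth_fundus({c}, size=64, seed=900 + i), {c})
        for i, c in enumerate(DESK_CLASSES * 20)
    ]


@pytest.fixture(scope="session")
def desk_model(desk_dataset):
    """Contrastive model trained at desk scale (seeded, < 1 s)."""
    return train(desk_dataset,
                 TrainConfig(epochs=60, lr=0.01, batch_size=64, seed=0))
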