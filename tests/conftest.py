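import numpy as np
import pytest

import stromalyzer as st
from stromalyzer.classes import TISSUE_CLASSES


@pytest.fixture(scope="session")
def trained_model():
    """A patch classifier trained on two synthetic slides per class."""
    tiles = [st.generate_tile({int(c)}, 384, 0.455, seed=s * 16 + int(c))
             for s in range(2) for c in TISSUE_CLASSES]
    return st.train_segmenter(tiles, st.TrainConfig(epochs=30), seed=0)


@pytest.fixture(scope="session")
def nine_class_tile():
    return st.generate_tile(set(int(c) for c in TISSUE_CLASSES), 512, 0.455,
                            seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
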