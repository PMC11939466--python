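import numpy as np
import pytest

from oednet.network import make_architecture
from oednet.synthetic import SyntheticConfig, generate_library
from oednet.training import TrainingConfig, train_network


#: Desk-scale study conditions: 96x96 patches, three conv blocks.
REDUCED_SYNTH = SyntheticConfig(
    image_size=288, patch_size=96, n_images=16, seed=3, stride=48,
    row_spacing=10, dot_spacing=8, dot_radius=2,
)

REDUCED_ARCH = make_architecture(channels=(8, 16, 32), h1=64, input_side=96)

REDUCED_TRAINING = TrainingConfig(epochs=24, batch_size=32, seed=0,
                                  lr_halving_period=10)

#: Miniature conditions for fast unit tests: 32x32 patches, one conv block.
TINY_SYNTH = SyntheticConfig(
    image_size=96, patch_size=32, n_images=8, seed=7, stride=16,
    row_spacing=8, dot_spacing=6, dot_radius=2, positive_fraction=0.4,
)

TINY_ARCH = make_architecture(channels=(8,), h1=16, input_side=32)


@pytest.fixture(scope="session")
def reduced_library():
    return generate_library(REDUCED_SYNTH)


@pytest.fixture(scope="session")
def tiny_library():
    return generate_library(TINY_SYNTH)


@pytest.fixture(scope="session")
def trained_reduced_model(reduced_library):
    """One reduced-scale model fitted on the synthetic library; shared by
    the learnability and detection checks."""
    net, log = train_network(reduced_library.train_signatures, REDUCED_ARCH,
                             REDUCED_TRAINING)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(0)
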