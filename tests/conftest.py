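import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_smear_batch():
    """24 synthetic 48x48 images (12 per class), session-cached."""
    from pidsan.synth import synthetic_dataset

    images, labels, truths = synthetic_dataset(12, 12, image_size=48, seed=11)
    return images, labels, truths
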