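import numpy as np
import pytest

from focirad import foci_pipeline as fp
from focirad import synthetic_data as syn
from focirad.pipeline_training import train_default_classifier


@pytest.fixture(scope="session")
def classifier() -> fp.FociClassifier:
    """Focus classifier trained once on a synthetic dose/time grid."""
    return train_default_classifier(np.random.default_rng(42), n_nuclei=18)


@pytest.fixture(scope="session")
def small_stack():
    """One 2 Gy / 60 min stack with 4 nuclei plus its ground truth."""
    rng = np.random.default_rng(11)
    return syn.simulate_stack(2.0, 60.0, 4, rng=rng)


@pytest.fixture(scope="session")
def small_label_map(small_stack):
    stack, _ = small_stack
    return fp.segment_nuclei(stack)
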