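import numpy as np
import pytest

from histocascade import stain as st
from histocascade import synthetic as syn


@pytest.fixture(scope="session")
def he_matrix():
    return st.default_he_matrix()


@pytest.fixture(scope="session")
def be_spec():
    return next(s for s in syn.default_class_specs() if s.label == "BE")


@pytest.fixture(scope="session")
def sample_roi(be_spec):
    """One low-noise benign-epithelium tile with ground truth."""
    return syn.generate_roi(be_spec, 128, 128, seed=42)


@pytest.fixture(scope="session")
def benchmark_rois():
    """40 tiles with well-separated nuclei (4 specs x 10 seeds)."""
    items = []
    for i, spec in enumerate(syn.detection_benchmark_specs()):
        for j in range(10):
            items.append(
                syn.generate_roi(spec, 128, 128, seed=syn.derive_seed(7, i * 10 + j))
            )
    return items


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
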