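import numpy as np
import pytest

from earaam.model import EarAAM
from earaam.scheme import load_acupoints, load_atlas, load_scheme
from earaam.synthetic import SynthesisParams, generate_dataset, generate_template


@pytest.fixture(scope="session")
def scheme():
    return load_scheme()


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def registry():
    return load_acupoints()


@pytest.fixture(scope="session")
def template():
    return generate_template()


@pytest.fixture(scope="session")
def std_dataset():
    """Twelve standard-profile synthetic samples (shared across tests)."""
    return generate_dataset(12, SynthesisParams.standard(seed=7))


@pytest.fixture(scope="session")
def small_aam(std_dataset):
    """An AAM trained on ten standard synthetic images (two held out)."""
    imgs, lms, boxes = std_dataset
    return EarAAM(n_levels=2).fit(imgs[:10], lms[:10], boxes=boxes[:10])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
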