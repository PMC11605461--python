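import numpy as np
import pytest

from pathdx.curation import load_demo_code_map
from pathdx.model import SequenceModel, SequenceModelConfig
from pathdx.pathways import Vocabulary
from pathdx.synthetic import desk_config, generate_cohort


@pytest.fixture(scope="session")
def demo_map():
    return load_demo_code_map()


@pytest.fixture(scope="session")
def small_cohort():
    """A small marginal-shift desk cohort shared by read-only tests."""
    return generate_cohort(desk_config(n_patients=300, seed=7))


@pytest.fixture(scope="session")
def small_vocab(small_cohort):
    return Vocabulary.from_groups(small_cohort.code_map.vocabulary)


@pytest.fixture(scope="session")
def tiny_model():
    """Small double-precision model for numerical checks."""
    return SequenceModel(
        SequenceModelConfig.desk(vocab_size=30, dtype="float64"), seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
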