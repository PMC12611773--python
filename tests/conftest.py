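import numpy as np
import pytest

from softalign.synthetic import AnnotatorModel, generate_hierarchy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_space():
    """2 superordinates x 2 basics x 3 items, well separated."""
    return generate_hierarchy(2, 2, 3, 8, (10.0, 2.0, 0.5), seed=1)


@pytest.fixture(scope="session")
def separated_space():
    """Larger, strongly separated space for recovery experiments."""
    return generate_hierarchy(3, 2, 6, 6, (8.0, 1.5, 0.3), seed=7)


@pytest.fixture
def deterministic_annotator():
    return AnnotatorModel(temperature=1e-6, lapse_rate=0.0, rt_noise_sd=0.0)
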