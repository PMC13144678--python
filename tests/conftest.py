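import numpy as np
import pytest

from promplace.corpus import generate_synthetic_corpus
from promplace.placeback import PlaceBackConfig, build_placeback
from promplace.samples import GeneratorConfig, sample_stream


@pytest.fixture(scope="session")
def corpus():
    """Small synthetic promoter corpus with 5' context for sample generation."""
    return generate_synthetic_corpus(60, promoter_length=400, gc_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def annotated_corpus():
    return generate_synthetic_corpus(30, promoter_length=400, plant_elements=True, seed=12)


@pytest.fixture(scope="session")
def placeback_quad():
    """Four untrained test-scale place-back models, msrl pattern (5, 5, 40, 40)."""
    return [
        build_placeback(PlaceBackConfig.test_scale(msrl, seed=seed))
        for msrl, seed in ((5, 0), (5, 1), (40, 2), (40, 3))
    ]


@pytest.fixture(scope="session")
def samples_msrl40(corpus):
    stream = sample_stream(corpus, GeneratorConfig(msrl=40), batch_size=20, seed=5)
    return next(stream)


@pytest.fixture(scope="session")
def samples_msrl5(corpus):
    stream = sample_stream(corpus, GeneratorConfig(msrl=5), batch_size=20, seed=6)
    return next(stream)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
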