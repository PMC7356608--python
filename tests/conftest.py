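import numpy as np
import pytest

from omcboost import BoosterConfig, SyntheticCaseSpec, generate_case

#: Reduced-tree configuration for test speed; the shipped default stays at 700.
FAST = BoosterConfig(n_trees=50)

#: Deliberately strong planted-signal generator for machinery tests: few
#: competing features and large effects so feature recovery is unambiguous.
STRONG_SPEC = dict(
    m=45, p=40, k_true=5, effect_sizes=(2.0, 2.0, 1.5, 1.5, 1.2), noise_sd=0.3
)


@pytest.fixture
def fast_config():
    return FAST


@pytest.fixture
def strong_case():
    """A clear planted-signal case plus its ground truth."""
    return generate_case(SyntheticCaseSpec(seed=300, **STRONG_SPEC))


@pytest.fixture
def null_case():
    """A pure-null case: the response is independent of every feature."""
    return generate_case(
        SyntheticCaseSpec(m=45, p=40, k_true=0, effect_sizes=(), noise_sd=0.5, seed=301)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
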