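import numpy as np
import pytest

import neuromimetic as nm


@pytest.fixture
def small_dataset():
    """Desk-scale imbalanced two-class table with 8 informative of 16 features."""
    return nm.generate(nm.GeneratorSpec(
        n_class0=90, n_class1=60, n_features=16, n_informative=8,
        effect_size=1.5, seed=7))


@pytest.fixture
def separable_dataset():
    """Strongly separated classes (effect size 3): near-zero Bayes error."""
    return nm.generate(nm.GeneratorSpec(
        n_class0=80, n_class1=60, n_features=10, n_informative=6,
        effect_size=3.0, correlation=0.0, seed=9))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
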