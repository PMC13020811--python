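import numpy as np
import pytest

from senesim.genome import TraitSpec, build_architecture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arch():
    """Two age-dependent traits over 5 age classes, 4 bits per block."""
    return build_architecture(
        [
            TraitSpec("survival", bits_per_block=4),
            TraitSpec("reproduction", bits_per_block=4, upper_bound=0.5),
            TraitSpec("mutation_rate", evolvable=False, age_dependent=False,
                      initial_value=0.001),
        ],
        n_age_classes=5,
    )
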