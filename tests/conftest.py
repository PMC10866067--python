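import numpy as np
import pytest

from linctools import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_annotation():
    """Toy genome with 5 genic / 10 intergenic / 3 non-neighboring lncRNAs."""
    return sim.make_annotation(sim.AnnotationSpec(seed=101))


@pytest.fixture(scope="session")
def small_counts():
    """600-feature NB counts with planted DE, high-expression and a module block."""
    spec = sim.CountSpec(
        seed=202, n_features=600, n_de=30, n_high=7,
        module_blocks=((40, 2.0, True),),
    )
    return sim.make_counts(spec)
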