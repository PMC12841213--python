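import numpy as np
import pytest

from iltcniche.synthetic import (make_reference, reference_signatures,
                                 simulate_section)


@pytest.fixture(scope="session")
def ref():
    return make_reference(seed=0)


@pytest.fixture(scope="session")
def signatures(ref):
    return reference_signatures(ref)


@pytest.fixture(scope="session")
def planted_section(ref):
    """One 500-spot section with layer-biased γδT and MAIT niches (10% of
    the whole section each)."""
    adata, truth = simulate_section(
        ref, n_spots=500,
        niche_spec={"dermis": {"gdT": 0.1 / 0.7},
                    "epidermis": {"MAIT": 0.1 / 0.3}},
        seed=0, sample="S1", group="L", pasi=12.0)
    return adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
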