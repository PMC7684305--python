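import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_refdb():
    from sedaforam.simulate import default_taxa, simulate_reference_db

    return simulate_reference_db(taxa=default_taxa(n_benthic=5), seed=7)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
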