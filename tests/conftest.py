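import numpy as np
import pytest

from rdnakit import synthetic_data as syn


@pytest.fixture(scope="session")
def default_arch():
    return syn.UnitArchitecture()


@pytest.fixture(scope="session")
def clean_locus(default_arch):
    """Error-free 10-unit array of 15 kb units with feature references."""
    genome, truth = syn.simulate_locus(default_arch, 10, seed=11)
    refs = syn.default_feature_references(default_arch, seed=11)
    return genome, truth, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
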