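import pytest

from treatminer.synthetic import SimConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 10-document noise-free synthetic corpus with its toy dictionaries."""
    return generate_corpus(SimConfig(seed=11, n_docs=10))


@pytest.fixture(scope="session")
def noisy_corpus():
    """A corpus with unknown taxa and unlinked values planted."""
    return generate_corpus(
        SimConfig(seed=13, n_docs=6, unknown_taxon_rate=0.3, unlinked_value_rate=0.2)
    )
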