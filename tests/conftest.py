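import pytest

from atoxfam.msa import blosum62_scheme
from atoxfam.simulate import default_config, generate_dataset


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def dataset():
    """Default 12-leaf synthetic family (0.05 subs/site per branch)."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def divergent_dataset():
    """Same family at 0.2 subs/site per branch (signature-mining regime)."""
    return generate_dataset(default_config(seed=1, rate=4.0))
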