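import pytest
from hypothesis import settings

from mitopop import genome_layout as gl
from mitopop import io_formats as iof
from mitopop import synthetic_data as syn

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chicken_features():
    return iof.load_chicken_features()


@pytest.fixture(scope="session")
def chicken_primers():
    return iof.load_chicken_primers()


@pytest.fixture(scope="session")
def chicken_layout(chicken_features):
    return gl.GenomeLayout(features=tuple(chicken_features), genome_length=16775)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic full-layout genome shared across tests."""
    genome, layout, truth = syn.make_genome(syn.SyntheticGenomeSpec(seed=7))
    return genome, layout, truth
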