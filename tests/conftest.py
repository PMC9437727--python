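import pytest

from miredit.simulate import make_locus


@pytest.fixture(scope="session")
def locus():
    """A reference tetraploid locus used across tests."""
    return make_locus(seed=1, n_alleles=4, snp_rate=0.01)


@pytest.fixture(scope="session")
def clean_locus():
    """A locus without allelic SNPs (single-allele behaviour)."""
    return make_locus(seed=2, n_alleles=4, snp_rate=0.0)
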