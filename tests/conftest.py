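import pytest

from anisketch import ANIParams, build_index, random_genome


@pytest.fixture(scope="session")
def base_genome_1mb():
    """One fixed 1 Mbp random genome shared by the heavy accuracy tests."""
    return random_genome(1_000_000, seed=1001, genome_id="base1mb")


@pytest.fixture(scope="session")
def base_index_1mb(base_genome_1mb):
    """Prebuilt minimizer index of the shared 1 Mbp genome (default params)."""
    return build_index(base_genome_1mb, ANIParams().sketch)


@pytest.fixture(scope="session")
def default_params():
    return ANIParams()
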