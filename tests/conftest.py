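import pytest

from snvconsensus import default_spec, simulate_genome, simulate_scores


@pytest.fixture(scope="session")
def genome_fixture():
    """Miniature genome with planted truth-known variants (both strands)."""
    return simulate_genome(seed=11, n_genes=6)


@pytest.fixture(scope="session")
def sim_data():
    """Default five-tool, five-category synthetic score dataset."""
    spec = default_spec(seed=7, n_per_class=200)
    datasets, table = simulate_scores(spec)
    return spec, datasets, table
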