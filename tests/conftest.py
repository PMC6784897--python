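import pytest

from metacomm import synthetic


@pytest.fixture(scope="session")
def small_community():
    """A 40-SG, 60-sample community with default planted effects."""
    params = synthetic.CommunitySimParams(n_sg=40, seed=11)
    tables, design, newick, truth = synthetic.simulate_community(params)
    return {
        "params": params,
        "tables": tables,
        "design": design,
        "newick": newick,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def genome_sim():
    """300 genomes with a 4x planted xoxF enrichment in the Increase group."""
    params = synthetic.GenomeSimParams(
        n_genomes=300,
        seed=7,
        planted_enrichments=[("xoxF", "Increase", 4.0)],
    )
    bins, functions, cazy, groups = synthetic.simulate_genomes(params)
    return {
        "params": params,
        "bins": bins,
        "functions": functions,
        "cazy": cazy,
        "groups": groups,
    }
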