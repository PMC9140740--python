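import pytest

from nbsurvey.synthetic_data import (
    SimulationConfig,
    simulate_gene_tree,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One light synthetic genome + gene tree shared by the unit tests."""
    d = tmp_path_factory.mktemp("fixtures")
    cfg = SimulationConfig.small()
    truth = simulate_genome(cfg, 11, d)
    tree_truth = simulate_gene_tree(cfg, 12, d)
    return d, cfg, truth, tree_truth
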