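import pytest

from panplastome.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One 6-taxon down-scaled simulation shared by read-only tests."""
    config = SimConfig(seed=11, n_taxa=6)
    ancestor, samples, truth = simulate(config)
    return config, ancestor, samples, truth


@pytest.fixture(scope="session")
def eight_taxon_sim():
    """A moderately diverged 8-taxon simulation for recovery tests."""
    config = SimConfig(seed=7, n_taxa=8, total_len=40_000, n_genes=30,
                       branch_len_mean=0.03)
    ancestor, samples, truth = simulate(config)
    return config, ancestor, samples, truth


@pytest.fixture()
def leaf_alignments(small_sim):
    _, _, samples, truth = small_sim
    leaves = [p.sample_id for p in samples]
    return {k: a.subset(leaves) for k, a in truth.true_alignments.items()}
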