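import numpy as np
import pytest

from deepsplit import GroupMap, SimulationConfig
from deepsplit.simulate import simulate_taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Small everything: 8 genomes, 6 genes, enough sites to recover trees."""
    return SimulationConfig(
        seed=5, n_arch_groups=2, n_eub_groups=2, genomes_per_group=2,
        n_universal_genes=6, sites_per_gene=500, n_families=12,
        proteins_per_genome=8, protein_length=120,
    )


@pytest.fixture
def tiny_taxonomy(tiny_config):
    group_map, species_tree = simulate_taxonomy(tiny_config)
    return tiny_config, group_map, species_tree


@pytest.fixture
def flat_group_map():
    """Hand-built map: 2 archaebacterial + 2 eubacterial groups, 2 genomes each."""
    mapping = {}
    for grp in ("archA", "archB"):
        for i in (1, 2):
            mapping[f"{grp}_g{i}"] = ("archaebacteria", grp)
    for grp in ("eubA", "eubB"):
        for i in (1, 2):
            mapping[f"{grp}_g{i}"] = ("eubacteria", grp)
    return GroupMap(mapping)
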