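"""Shared fixtures: simulated datasets and trained models at two scales.

``micro_*`` fixtures are 4-species/48-record datasets with small embeddings,
fast enough for per-test training; ``toy_*`` fixtures are the 32-species
default simulation with a scaled grouping threshold so the hierarchy has
routing nodes, Other leaves and species leaves.
"""

import pytest

from hftc.classify import FeatureConfig, ForestConfig, train_hftc
from hftc.curation import CurationConfig, curate
from hftc.hierarchy import HierarchyConfig
from hftc.simulate import SimConfig, generate_dataset, generate_holdout

MICRO_SIM = dict(
    n_phyla=2, classes_per_phylum=1, orders_per_class=1, families_per_order=1,
    genera_per_family=1, species_per_genus=2, seq_length=200,
    ambiguous_fraction=0.0, nonacgt_fraction=0.0, seed=11,
)

SMALL_EMBED = dict(n_dims=16, epochs=2, seed=5)


@pytest.fixture(scope="session")
def micro_dataset():
    """4 species × 12 records, 200 bp, no noise; curated to 40 records."""
    return curate(generate_dataset(SimConfig(**MICRO_SIM)), CurationConfig(seed=3))


@pytest.fixture(scope="session")
def toy_sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def toy_dataset(toy_sim_config):
    """The default simulation (32 species, 400 records incl. noise), curated."""
    return curate(generate_dataset(toy_sim_config), CurationConfig(seed=1))


@pytest.fixture(scope="session")
def toy_holdout(toy_sim_config):
    return generate_holdout(toy_sim_config, 3)


@pytest.fixture(scope="session")
def toy_model(toy_dataset):
    """Hierarchical model on the toy data: threshold scaled to 4 species so
    routing nodes, Other grouping and species leaves all appear."""
    return train_hftc(
        toy_dataset,
        HierarchyConfig(group_threshold=4),
        FeatureConfig(**SMALL_EMBED),
        ForestConfig(seed=5),
    )
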