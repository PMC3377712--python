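"""Shared fixtures: a reference world and a cohort at study-like settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vaginome import classify, synthetic

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

WORLD_SEED = 11


@pytest.fixture(scope="session")
def world():
    """12-taxon reference world with 4 sequences per taxon."""
    return synthetic.simulate_reference_world(
        n_taxa=12, seqs_per_taxon=4, seq_length=300, seed=WORLD_SEED
    )


@pytest.fixture(scope="session")
def effect(world):
    eff = synthetic.EffectConfig.default(world.species)
    eff.depth_mean = 150.0  # desk-scale depth for the shared cohort
    return eff


@pytest.fixture(scope="session")
def cohort(effect):
    """60-sample mixed cohort (45% BV) with metadata."""
    meta, counts = synthetic.simulate_cohort(
        60, 0.45, {"White": 0.44, "Black": 0.34, "Other": 0.22},
        effect, seed=WORLD_SEED + 1,
    )
    return meta, counts


@pytest.fixture(scope="session")
def placements(world, cohort):
    _, counts = cohort
    return synthetic.simulate_placements(counts, world, 0.03, seed=WORLD_SEED + 2)


@pytest.fixture(scope="session")
def edge_labels(world):
    return classify.label_edges(world.tree, world.taxonomy, world.leaf_taxids)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
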