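import numpy as np
import pytest

from pathreverse import (
    RankedSignature,
    ReversalQuery,
    SimulationConfig,
    make_pathway_collection,
)


@pytest.fixture
def six_gene_ranked() -> RankedSignature:
    """The hand-checkable worked example: stats 3, 2, 1, -1, -2, -3."""
    return RankedSignature(
        "toy",
        ["g1", "g2", "g3", "g4", "g5", "g6"],
        np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]),
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=1000,
        n_pathways=10,
        pathway_size_range=(20, 60),
        planted_disease={"PW001": ("UP", 2.0), "PW002": ("DOWN", 2.0)},
        n_compounds=12,
        signatures_per_compound=2,
        planted_reversers=frozenset({"CPD0001", "CPD0002"}),
        seed=11,
    )


@pytest.fixture
def small_collection(small_config):
    return make_pathway_collection(small_config)


@pytest.fixture
def small_query() -> ReversalQuery:
    return ReversalQuery({"PW001": "DOWN", "PW002": "UP"})
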