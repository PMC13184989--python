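import numpy as np
import pytest

from bulgeselect.enrichment import merge_common
from bulgeselect.library_model import (
    DegenerateLibrarySpec,
    PairConstraint,
    default_bulge_spec,
)
from bulgeselect.ml_model import NetworkConfig
from bulgeselect.selection_sim import make_benchmark


@pytest.fixture(scope="session")
def spec():
    return default_bulge_spec()


@pytest.fixture(scope="session")
def tiny_spec():
    """4 variable positions (one constrained pair), 64 genotypes."""
    return DegenerateLibrarySpec(
        core_length=8,
        variable_positions=(2, 3, 5, 7),
        position_codes={3: "N", 5: "N"},
        pair_constraints=(PairConstraint(pos5=2, pos3=7),),
        reference_core="AXXGXCXT",
    )


@pytest.fixture(scope="session")
def fast_config():
    """Reduced network for test-budget fits; architecture family unchanged."""
    return NetworkConfig(
        hidden_layer_sizes=(64, 64), alpha=1e-4, batch_size=200, max_iter=60
    )


@pytest.fixture(scope="session")
def additive_bench():
    return make_benchmark("additive", seed=11)


@pytest.fixture(scope="session")
def additive_merged(additive_bench):
    return merge_common(
        additive_bench.post_counts["A"], additive_bench.post_counts["B"]
    )


@pytest.fixture(scope="session")
def imbalanced_bench():
    return make_benchmark("imbalanced", seed=21)


@pytest.fixture(scope="session")
def imbalanced_merged(imbalanced_bench):
    return merge_common(
        imbalanced_bench.post_counts["A"], imbalanced_bench.post_counts["B"]
    )


@pytest.fixture(scope="session")
def planted_bench():
    return make_benchmark("specificity-planted", seed=7)


@pytest.fixture(scope="session")
def planted_merged(planted_bench):
    return merge_common(
        planted_bench.post_counts["A"], planted_bench.post_counts["B"]
    )
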