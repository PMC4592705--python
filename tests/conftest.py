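import numpy as np
import pytest

from ribomech import coarse_grain, make_toy_protein_chain, make_toy_rna_chain
from ribomech.synthetic import (
    FixtureSpec,
    component_selections,
    make_balanced_assembly,
    ptc_selection_of,
)


@pytest.fixture(scope="session")
def protein_chain_10():
    return make_toy_protein_chain(10, seed=11)


@pytest.fixture(scope="session")
def protein_nodes_10(protein_chain_10):
    return coarse_grain(protein_chain_10)


@pytest.fixture(scope="session")
def rna_chain_10():
    return make_toy_rna_chain(10, seed=12)


@pytest.fixture(scope="session")
def balanced():
    """Balanced two-appendage assembly with its analytic ground truth."""
    spec = FixtureSpec(seed=7)
    structure, gt = make_balanced_assembly(spec)
    nodes = coarse_grain(structure, component_selections(gt))
    return structure, nodes, gt, ptc_selection_of(gt)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
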