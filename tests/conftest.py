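import pytest

import phylocore as pc


@pytest.fixture(scope="session")
def fig_a():
    return pc.fig1_fixture("A")


@pytest.fixture(scope="session")
def fig_b():
    return pc.fig1_fixture("B")


@pytest.fixture(scope="session")
def comb_tree():
    # hand-built balanced tree with easy arithmetic
    return pc.LabeledTree.from_newick("((SA:1,SB:1)G1:1,(SC:1,SD:1)G2:1)F;")


@pytest.fixture(scope="session")
def regional_params():
    return pc.ScenarioParams(pool_size=256)
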