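import numpy as np
import pytest

from phylocomp.regimes import MkModel
from phylocomp.simulate import (
    simulate_bd_tree,
    simulate_biogeo_history,
    simulate_regime_history,
)
from phylocomp.tree import parse_newick, uniform_history

REGIMES = ("tropical", "temperate")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_regimes(three_tip):
    return uniform_history(three_tip, "tropical", REGIMES)


@pytest.fixture
def mk2():
    """Symmetric 2-state switch model at a moderate rate."""
    Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
    return MkModel(REGIMES, Q)


def random_fixture(seed, n_tips=5, height=1.0, n_areas=0, switch=0.5):
    """A small random (tree, regimes, biogeo) triple for battery tests."""
    tree = simulate_bd_tree(n_tips, birth=0.5, death=0.1, seed=seed)
    tree = tree.rescale(height)
    Q = np.array([[-switch, switch], [switch, -switch]])
    mk = MkModel(REGIMES, Q)
    regimes = simulate_regime_history(tree, mk, seed=seed + 1000)
    biogeo = None
    if n_areas:
        biogeo = simulate_biogeo_history(tree, n_areas, gain=1.0, loss=1.0,
                                         seed=seed + 2000)
    return tree, regimes, biogeo
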