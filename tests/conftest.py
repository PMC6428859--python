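import numpy as np
import pytest

from morphorates import Phylogeny, simulate_yule_tree


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); -- C = [[2,1,0],[1,2,0],[0,0,2]] by hand."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule33() -> Phylogeny:
    """A 33-tip unit-depth pure-birth tree shared across statistical tests."""
    return simulate_yule_tree(33, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def circle_points(radius: float = 1.0, n: int = 256, phase: float = 0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])
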