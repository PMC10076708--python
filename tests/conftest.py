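import numpy as np
import pytest

from mdgan.data import AssociationMatrix, DiseaseDAG, DiseaseGeneAnnotation, GeneNetwork
from mdgan.synthetic import FixtureSpec, make_full_fixture


@pytest.fixture
def identity_am():
    """2 diseases x 2 microbes with an identity association pattern."""
    return AssociationMatrix(["d1", "d2"], ["m1", "m2"], np.eye(2))


@pytest.fixture
def small_am():
    """3 diseases x 4 microbes with mixed profiles."""
    A = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    return AssociationMatrix(["d1", "d2", "d3"], ["m1", "m2", "m3", "m4"], A)


@pytest.fixture
def sibling_dag():
    """Root r with children b and c (the sibling configuration)."""
    return DiseaseDAG(["r", "b", "c"], {("r", "b"), ("r", "c")})


@pytest.fixture
def chain_shortcut_dag():
    """Chain r -> a -> dt plus the shortcut edge r -> dt."""
    return DiseaseDAG(["r", "a", "dt"], {("r", "a"), ("a", "dt"), ("r", "dt")})


@pytest.fixture
def two_gene_net():
    """g1-g2 at the maximum LLS, g2-g3 at the minimum."""
    return GeneNetwork({frozenset(("g1", "g2")): 3.0, frozenset(("g2", "g3")): 1.0})


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-block study conditions, generated once."""
    return make_full_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_fixture():
    """A scaled-down planted-block fixture for fast end-to-end checks."""
    spec = FixtureSpec(nd=12, nm=16, n_blocks=2, within_density=0.4,
                       background_density=0.02, gene_count=16, seed=7)
    return make_full_fixture(spec)


def random_association(rng: np.random.Generator, nd: int, nm: int) -> AssociationMatrix:
    """Random binary association matrix with at least one positive."""
    A = (rng.random((nd, nm)) < 0.3).astype(float)
    if A.sum() == 0:
        A[rng.integers(nd), rng.integers(nm)] = 1.0
    return AssociationMatrix(
        [f"d{i}" for i in range(nd)], [f"m{j}" for j in range(nm)], A
    )


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseDAG:
    """Random DAG: each node gets parents among lower-numbered nodes."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = set()
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < 0.4:
                edges.add((nodes[j], nodes[i]))
    return DiseaseDAG(nodes, edges)
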