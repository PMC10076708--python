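"""Synthetic fixtures shaped like curated microbe-disease inputs.

Three generators cover every input the pipeline consumes:

* a planted-block binary association matrix — diseases and microbes fall
  into matched groups and associations concentrate inside matched groups,
  giving a known recoverable structure for link prediction;
* a scored random gene network plus disease-gene annotations whose overlap
  follows the same block structure, so functional disease similarity
  correlates with the planted blocks;
* a rooted random disease DAG that places same-block diseases under shared
  subtrees, so semantic similarity correlates with the blocks too.

The default sizes (40 diseases x 60 microbes, 4 blocks, within-block
density 0.25 over a 0.01 background) land in the same positive-count range
as small curated association databases (a few hundred known pairs) while
staying desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneAnnotation,
    GeneNetwork,
    write_annotations,
    write_associations,
    write_dag,
    write_gene_network,
)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    nd: int = 40
    nm: int = 60
    n_blocks: int = 4
    within_density: float = 0.25
    background_density: float = 0.01
    gene_count: int = 48
    gene_edge_prob: float = 0.15
    lls_range: tuple[float, float] = (0.5, 5.0)
    annotation_overlap: float = 0.8
    dag_depth: int = 2
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_density < self.within_density <= 1.0):
            raise ValueError("require 0 <= background_density < within_density <= 1")
        if self.lls_range[0] >= self.lls_range[1]:
            raise ValueError("lls_range must satisfy min < max")
        for name in ("nd", "nm", "n_blocks", "gene_count", "dag_depth", "dag_branching"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def disease_blocks(self) -> list[np.ndarray]:
        return np.array_split(np.arange(self.nd), self.n_blocks)

    def microbe_blocks(self) -> list[np.ndarray]:
        return np.array_split(np.arange(self.nm), self.n_blocks)


def _block_of(blocks: list[np.ndarray], idx: int) -> int:
    for b, members in enumerate(blocks):
        if idx in members:
            return b
    raise IndexError(idx)


def make_association_fixture(spec: FixtureSpec) -> AssociationMatrix:
    """Planted-block Bernoulli association matrix.

    Cell probability is ``within_density`` when the disease and microbe
    belong to matched blocks, ``background_density`` otherwise.  Draws are
    regenerated wholesale (up to 100 times) until every row and column has
    at least one positive, keeping the cell distribution clean.
    """
    rng = np.random.default_rng(spec.seed)
    d_blocks, m_blocks = spec.disease_blocks(), spec.microbe_blocks()
    P = np.full((spec.nd, spec.nm), spec.background_density)
    for b in range(spec.n_blocks):
        P[np.ix_(d_blocks[b], m_blocks[b])] = spec.within_density
    for _ in range(100):
        A = (rng.random((spec.nd, spec.nm)) < P).astype(float)
        if A.sum(axis=1).min() > 0 and A.sum(axis=0).min() > 0:
            diseases = [f"disease_{i:03d}" for i in range(spec.nd)]
            microbes = [f"microbe_{j:03d}" for j in range(spec.nm)]
            return AssociationMatrix(diseases, microbes, A)
    raise RuntimeError(
        "could not generate a matrix with nonempty rows/columns in 100 draws; "
        "densities too low for the requested size"
    )


def make_gene_fixture(
    spec: FixtureSpec, diseases: list[str]
) -> tuple[GeneNetwork, DiseaseGeneAnnotation]:
    """Random scored gene network plus block-structured annotations.

    Genes split into one core pool per block; a disease takes each gene of
    its block's pool with probability ``annotation_overlap`` and each
    foreign gene with a small leak probability scaled by
    ``1 - annotation_overlap``, so same-block diseases share genes.  Edge
    scores are uniform on ``lls_range`` over an Erdos-Renyi graph.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)).generate_state(1)[0])
    genes = [f"gene_{g:03d}" for g in range(spec.gene_count)]
    pools = np.array_split(np.arange(spec.gene_count), spec.n_blocks)
    d_blocks = spec.disease_blocks()

    edges: dict[frozenset, float] = {}
    lo, hi = spec.lls_range
    for a in range(spec.gene_count):
        for b in range(a + 1, spec.gene_count):
            if rng.random() < spec.gene_edge_prob:
                edges[frozenset((genes[a], genes[b]))] = float(rng.uniform(lo, hi))
    if not edges:  # guarantee a scorable network even at tiny sizes
        edges[frozenset((genes[0], genes[1]))] = float(rng.uniform(lo, hi))
    net = GeneNetwork(edges)

    leak = 0.05 * (1.0 - spec.annotation_overlap)
    sets: dict[str, frozenset] = {}
    for i, d in enumerate(diseases[: spec.nd]):
        pool = pools[_block_of(d_blocks, i)]
        chosen = {genes[g] for g in pool if rng.random() < spec.annotation_overlap}
        chosen |= {
            genes[g]
            for g in range(spec.gene_count)
            if g not in pool and rng.random() < leak
        }
        if not chosen:
            chosen = {genes[pool[0]]}
        sets[d] = frozenset(chosen)
    return net, DiseaseGeneAnnotation(sets)


def make_dag_fixture(spec: FixtureSpec, diseases: list[str]) -> DiseaseDAG:
    """Rooted disease ontology with same-block diseases under shared subtrees.

    Each block owns a spine of ``dag_depth - 1`` internal nodes hanging
    under the root; when ``dag_branching > 1`` the spine fans out into that
    many sibling anchors and block members attach under random anchors,
    otherwise they attach to the spine end directly.  Because the whole
    block shares its spine, within-block semantic similarity always exceeds
    the cross-block value, whichever anchors members land on.
    ``dag_depth == 1`` degenerates to a star: every disease a direct child
    of the root, all pairwise similarities 1/3.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)).generate_state(1)[0])
    root = "ontology_root"
    edges: set[tuple[str, str]] = set()
    nodes: list[str] = [root]
    d_blocks = spec.disease_blocks()
    for b in range(spec.n_blocks):
        members = [diseases[i] for i in d_blocks[b]]
        if spec.dag_depth == 1:
            edges.update((root, d) for d in members)
            continue
        parent = root
        for lvl in range(spec.dag_depth - 1):
            node = f"branch_{b}_{lvl}"
            edges.add((parent, node))
            nodes.append(node)
            parent = node
        if spec.dag_branching > 1:
            anchors = [f"anchor_{b}_{a}" for a in range(spec.dag_branching)]
            for a in anchors:
                edges.add((parent, a))
                nodes.append(a)
            for d in members:
                edges.add((anchors[int(rng.integers(len(anchors)))], d))
        else:
            edges.update((parent, d) for d in members)
    nodes.extend(diseases)
    return DiseaseDAG(nodes, edges)


def make_full_fixture(spec: FixtureSpec):
    """All three fixtures from one spec: (associations, gene net, annotations, dag)."""
    am = make_association_fixture(spec)
    net, ann = make_gene_fixture(spec, am.diseases)
    dag = make_dag_fixture(spec, am.diseases)
    return am, net, ann, dag


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as the four TSV inputs the loaders consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    am, net, ann, dag = make_full_fixture(spec)
    paths = {
        "associations": out / "associations.tsv",
        "gene_network": out / "gene_network.tsv",
        "annotations": out / "annotations.tsv",
        "dag": out / "disease_dag.tsv",
    }
    write_associations(am, paths["associations"])
    write_gene_network(net, paths["gene_network"])
    write_annotations(ann, paths["annotations"])
    write_dag(dag, paths["dag"])
    return paths
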