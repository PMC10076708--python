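"""Similarity views over diseases and microbes, and their fusion.

Three views exist per entity axis:

* **GIP** — Gaussian interaction profile kernel on binary association
  profiles, ``exp(-lambda * ||p_i - p_j||^2)`` with the bandwidth ``lambda``
  normalised by the mean squared profile norm.
* **cosine** — cosine of the angle between association profiles (0 by
  convention for an all-zero profile).
* **functional** — for diseases, gene-set agreement through a scored
  gene-interaction network (min-max-normalised LLS as the pairwise gene
  score); for microbes, agreement of the associated disease sets through
  DAG-based semantic similarity with a 0.5 per-generation decay.

The per-axis views average elementwise into a fused matrix, and the fused
disease block ``DS``, the association block ``A``, and the fused microbe
block ``MS`` assemble into the heterogeneous network
``Y = [[DS, A], [A^T, MS]]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import AssociationMatrix, DiseaseDAG, DiseaseGeneAnnotation, GeneNetwork

_SYM_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square, symmetric, labeled similarity view over one entity axis."""

    entity_ids: list[str]
    S: np.ndarray
    view_name: str

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.entity_ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.S.shape} != ({n}, {n})")
        if not np.allclose(self.S, self.S.T, rtol=0.0, atol=_SYM_TOL):
            raise ValueError(f"{self.view_name}: matrix not symmetric within {_SYM_TOL}")


@dataclass
class HeterogeneousNetwork:
    """Block matrix ``[[DS, A], [A^T, MS]]`` over diseases then microbes."""

    Y: np.ndarray
    diseases: list[str]
    microbes: list[str]

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def nm(self) -> int:
        return len(self.microbes)

    @property
    def block_layout(self) -> dict:
        nd, nm = self.nd, self.nm
        return {
            "disease_range": (0, nd),
            "microbe_range": (nd, nd + nm),
            "DS": ((0, nd), (0, nd)),
            "A": ((0, nd), (nd, nd + nm)),
            "At": ((nd, nd + nm), (0, nd)),
            "MS": ((nd, nd + nm), (nd, nd + nm)),
        }

    @property
    def association_block(self) -> np.ndarray:
        return self.Y[: self.nd, self.nd :]


def _profiles(am: AssociationMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "disease":
        return am.A, list(am.diseases)
    if axis == "microbe":
        return am.A.T, list(am.microbes)
    raise ValueError(f"axis must be 'disease' or 'microbe', got {axis!r}")


def gip_similarity(am: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity along one axis.

    ``S_ij = exp(-lam * ||p_i - p_j||^2)`` where ``lam`` is the reciprocal of
    the mean squared profile norm over the axis.  For binary profiles the
    squared Euclidean norm equals the row sum.
    """
    P, ids = _profiles(am, axis)
    sq_norms = (P**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ZeroDivisionError("GIP bandwidth undefined (division by zero): all profiles are zero")
    lam = 1.0 / mean_sq
    # ||p_i - p_j||^2 via the Gram expansion; clip tiny negatives from rounding
    G = P @ P.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * G
    np.clip(d2, 0.0, None, out=d2)
    S = np.exp(-lam * d2)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(ids, S, "gip")


def cosine_similarity(am: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Cosine similarity of association profiles; zero profiles map to 0."""
    P, ids = _profiles(am, axis)
    norms = np.sqrt((P**2).sum(axis=1))
    G = P @ P.T
    denom = norms[:, None] * norms[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0.0, G / np.where(denom > 0.0, denom, 1.0), 0.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(ids, S, "cosine")


def gene_functional_score(gp: str, gq: str, net: GeneNetwork) -> float:
    """Pairwise gene functional score FSS.

    1 for identical genes; the min-max-normalised LLS for adjacent genes;
    0 for non-adjacent pairs (absence of evidence contributes no link).
    """
    if gp == gq:
        return 1.0
    lls = net.score(gp, gq)
    if lls is None:
        return 0.0
    lo, hi = net.lls_min, net.lls_max
    if hi == lo:
        raise ZeroDivisionError("degenerate LLS range: lls_max == lls_min")
    return (lls - lo) / (hi - lo)


def _best_match(g: str, others: frozenset, net: GeneNetwork) -> float:
    return max(gene_functional_score(g, o, net) for o in others)


def disease_functional_similarity(
    ann: DiseaseGeneAnnotation,
    net: GeneNetwork,
    diseases: Sequence[str],
) -> SimilarityMatrix:
    """Disease functional similarity from annotated gene sets.

    ``DFS(di, dj)`` averages, over both gene sets, each gene's best match in
    the other set.  A disease with no annotation scores 0 against every
    other disease (diagonal forced to 1); a warning reports the coverage gap.
    """
    n = len(diseases)
    sets = [ann.genes_of(d) for d in diseases]
    missing = [d for d, s in zip(diseases, sets) if not s]
    if missing:
        warnings.warn(f"diseases without gene annotation (functional similarity 0): {missing}")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            Gi, Gj = sets[i], sets[j]
            if not Gi or not Gj:
                continue
            total = sum(_best_match(g, Gj, net) for g in Gi)
            total += sum(_best_match(g, Gi, net) for g in Gj)
            S[i, j] = S[j, i] = total / (len(Gi) + len(Gj))
    return SimilarityMatrix(list(diseases), S, "functional")


def semantic_contribution(dag: DiseaseDAG, dt: str) -> dict[str, float]:
    """Semantic contribution of every node in ``V_dt`` to the disease ``dt``.

    ``SC_dt(dt) = 1``; each ancestor's contribution is 0.5 times the best
    contribution among its children inside ``V_dt`` (Wang-style decay).
    """
    if dt not in dag:
        raise KeyError(f"disease {dt!r} not in DAG")
    V = dag.ancestors(dt)
    sc: dict[str, float] = {}

    def rec(node: str) -> float:
        if node in sc:
            return sc[node]
        if node == dt:
            sc[node] = 1.0
        else:
            kids = dag.children(node) & V
            sc[node] = max(0.5 * rec(k) for k in kids)
        return sc[node]

    for node in V:
        rec(node)
    return sc


def disease_semantic_similarity(dag: DiseaseDAG, di: str, dj: str) -> float:
    """DAG semantic similarity between two diseases.

    Shared-ancestor contributions from both sides, normalised by the two
    semantic values (sums of each disease's own contributions).
    """
    sci = semantic_contribution(dag, di)
    scj = semantic_contribution(dag, dj)
    shared = set(sci) & set(scj)
    num = sum(sci[d] + scj[d] for d in shared)
    den = sum(sci.values()) + sum(scj.values())
    return num / den


def microbe_functional_similarity(
    am: AssociationMatrix, dag: DiseaseDAG
) -> SimilarityMatrix:
    """Microbe functional similarity through associated disease sets.

    Each microbe is represented by the set of diseases it associates with;
    pairwise similarity averages each disease's best semantic match in the
    other set.  Diseases absent from the DAG count as isolated nodes, so
    they match only themselves.
    """
    nm = am.nm
    # isolated-node fallback for diseases missing from the ontology
    extra = [d for d in am.diseases if d not in dag]
    if extra:
        warnings.warn(f"diseases absent from DAG treated as isolated nodes: {extra}")
        dag = DiseaseDAG(list(dag.nodes) + extra, set(dag.parent_edges))
    dss = np.eye(am.nd)
    for i in range(am.nd):
        for j in range(i + 1, am.nd):
            dss[i, j] = dss[j, i] = disease_semantic_similarity(
                dag, am.diseases[i], am.diseases[j]
            )
    disease_sets = [np.nonzero(am.A[:, j])[0] for j in range(nm)]
    empty = [am.microbes[j] for j in range(nm) if disease_sets[j].size == 0]
    if empty:
        warnings.warn(f"microbes with no associated diseases (similarity 0): {empty}")
    S = np.zeros((nm, nm))
    for i in range(nm):
        Di = disease_sets[i]
        for j in range(i, nm):
            Dj = disease_sets[j]
            if Di.size == 0 or Dj.size == 0:
                continue
            sub = dss[np.ix_(Di, Dj)]
            total = sub.max(axis=0).sum() + sub.max(axis=1).sum()
            S[i, j] = S[j, i] = total / (Di.size + Dj.size)
    return SimilarityMatrix(list(am.microbes), S, "functional")


def fuse_views(*views: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of the supplied similarity views (order-checked)."""
    if not views:
        raise ValueError("at least one view required")
    ids = views[0].entity_ids
    for v in views[1:]:
        if v.entity_ids != ids:
            raise ValueError("views disagree on entity identifiers or order")
        if v.S.shape != views[0].S.shape:
            raise ValueError("views disagree on shape")
    S = np.mean([v.S for v in views], axis=0)
    return SimilarityMatrix(list(ids), S, "fused")


def integrated_similarities(
    am: AssociationMatrix,
    gene_net: GeneNetwork | None = None,
    annotations: DiseaseGeneAnnotation | None = None,
    dag: DiseaseDAG | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Compute fused disease (DS) and microbe (MS) similarity matrices.

    GIP and cosine views always enter the fusion; the functional views are
    included only when their auxiliary inputs (gene network + annotations
    for diseases, disease DAG for microbes) are provided.
    """
    d_views = [gip_similarity(am, "disease"), cosine_similarity(am, "disease")]
    if gene_net is not None and annotations is not None:
        d_views.append(disease_functional_similarity(annotations, gene_net, am.diseases))
    m_views = [gip_similarity(am, "microbe"), cosine_similarity(am, "microbe")]
    if dag is not None:
        m_views.append(microbe_functional_similarity(am, dag))
    return fuse_views(*d_views), fuse_views(*m_views)


def build_heterogeneous_network(
    DS: SimilarityMatrix, MS: SimilarityMatrix, am: AssociationMatrix
) -> HeterogeneousNetwork:
    """Assemble ``Y = [[DS, A], [A^T, MS]]`` with diseases indexed first."""
    nd, nm = am.nd, am.nm
    if DS.S.shape != (nd, nd):
        raise ValueError(f"DS shape {DS.S.shape} != ({nd}, {nd})")
    if MS.S.shape != (nm, nm):
        raise ValueError(f"MS shape {MS.S.shape} != ({nm}, {nm})")
    if DS.entity_ids != am.diseases or MS.entity_ids != am.microbes:
        raise ValueError("similarity id order does not match the association matrix")
    Y = np.block([[DS.S, am.A], [am.A.T, MS.S]])
    return HeterogeneousNetwork(Y, list(am.diseases), list(am.microbes))
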