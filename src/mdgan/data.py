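"""Readers, writers, and validated containers for association-network inputs.

The package consumes four plain-text table formats:

* association edge lists ``(disease, microbe)`` in the style of curated
  microbe-disease databases,
* scored gene-interaction edge lists ``(gene_a, gene_b, lls)`` carrying a
  log-likelihood score (LLS) per functional link,
* disease ontology parent->child edge lists defining a rooted DAG, and
* disease->gene annotation tables.

Identifier matching is exact-string and case-sensitive throughout; row and
column order is first-appearance order in the source file, so loading is
deterministic and round-trips exactly.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: column vocabularies used to auto-detect an optional header row
_HEADER_WORDS = {
    "disease", "microbe", "gene", "gene_a", "gene_b", "genea", "geneb",
    "lls", "score", "parent", "child", "source", "target",
}


class DataFormatError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_rows(
    path: str | Path,
    n_cols: int,
    delimiter: str | None = None,
    header: bool | str = "auto",
) -> list[tuple[int, list[str]]]:
    """Read an edge-list file into ``(line_number, fields)`` pairs.

    ``header='auto'`` drops the first row when all its fields belong to the
    known column vocabulary.  Rows with fewer than ``n_cols`` non-empty
    fields raise :class:`DataFormatError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise DataFormatError(f"{path}: file is empty")
    delim = delimiter or _sniff_delimiter(text[:4096])
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        rows.append((lineno, fields))
    if header == "auto":
        first = [f.lower().replace(" ", "_") for f in rows[0][1]]
        if all(f in _HEADER_WORDS for f in first):
            rows = rows[1:]
    elif header:
        rows = rows[1:]
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    for lineno, fields in rows:
        if len(fields) < n_cols or any(not f for f in fields[:n_cols]):
            raise DataFormatError(
                f"{path}: line {lineno}: expected {n_cols} non-empty "
                f"columns, got {fields!r}"
            )
    return rows


@dataclass
class AssociationMatrix:
    """Binary disease x microbe adjacency with ordered identifier registries.

    ``A[i, j] == 1`` iff disease ``diseases[i]`` has a known association with
    microbe ``microbes[j]``.
    """

    diseases: list[str]
    microbes: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        nd, nm = self.A.shape
        if len(self.diseases) != nd or len(self.microbes) != nm:
            raise DataFormatError("id registry lengths do not match matrix shape")
        if len(set(self.diseases)) != nd:
            raise DataFormatError("duplicate disease identifiers")
        if len(set(self.microbes)) != nm:
            raise DataFormatError("duplicate microbe identifiers")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise DataFormatError("association matrix must be binary")

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def nm(self) -> int:
        return len(self.microbes)

    @property
    def n_positives(self) -> int:
        return int(self.A.sum())

    def disease_index(self, disease: str) -> int:
        return self.diseases.index(disease)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.diseases), list(self.microbes), self.A.copy())

    def pairs(self) -> list[tuple[str, str]]:
        """Known (disease, microbe) pairs in row-major matrix order."""
        ii, jj = np.nonzero(self.A)
        return [(self.diseases[i], self.microbes[j]) for i, j in zip(ii, jj)]


@dataclass
class GeneNetwork:
    """Undirected gene-interaction graph with one LLS score per edge."""

    edges: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise DataFormatError(f"self-loop or malformed edge: {set(e)}")

    @property
    def genes(self) -> set[str]:
        return set().union(*self.edges) if self.edges else set()

    @property
    def lls_min(self) -> float:
        return min(self.edges.values())

    @property
    def lls_max(self) -> float:
        return max(self.edges.values())

    def score(self, ga: str, gb: str) -> float | None:
        """Raw LLS of the (ga, gb) edge, or None when not adjacent."""
        return self.edges.get(frozenset((ga, gb)))


@dataclass
class DiseaseGeneAnnotation:
    """Mapping disease identifier -> set of annotated genes (the sets G_i)."""

    gene_sets: dict[str, frozenset]

    def genes_of(self, disease: str) -> frozenset:
        return self.gene_sets.get(disease, frozenset())


@dataclass
class DiseaseDAG:
    """Rooted disease ontology fragment: directed parent->child edges.

    The ancestor set of a node (``V_dt``) includes the node itself, matching
    the convention used by DAG-based semantic similarity.
    """

    nodes: list[str]
    parent_edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.nodes)
        self._g.add_edges_from(self.parent_edges)
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise DataFormatError(f"ontology edges contain a cycle: {cycle}")
        self.nodes = list(self._g.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def ancestors(self, node: str) -> set[str]:
        """V_node: the node plus all its DAG ancestors."""
        if node not in self._g:
            raise KeyError(node)
        return nx.ancestors(self._g, node) | {node}

    def children(self, node: str) -> set[str]:
        return set(self._g.successors(node))


def load_associations(
    path: str | Path,
    dedup: bool = True,
    delimiter: str | None = None,
    header: bool | str = "auto",
) -> AssociationMatrix:
    """Load a ``(disease, microbe)`` edge list into a binary matrix.

    Duplicate pairs collapse to a single association when ``dedup`` is on
    (duplicates are an error otherwise).  Row/column order is the order of
    first appearance.
    """
    rows = _read_rows(path, 2, delimiter, header)
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for lineno, fields in rows:
        d, m = fields[0], fields[1]
        if (d, m) in seen:
            if not dedup:
                raise DataFormatError(f"{path}: line {lineno}: duplicate pair ({d}, {m})")
            continue
        seen.add((d, m))
        diseases.setdefault(d, len(diseases))
        microbes.setdefault(m, len(microbes))
        pairs.append((d, m))
    A = np.zeros((len(diseases), len(microbes)))
    for d, m in pairs:
        A[diseases[d], microbes[m]] = 1.0
    return AssociationMatrix(list(diseases), list(microbes), A)


def write_associations(am: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tmicrobe\n")
        for d, m in am.pairs():
            fh.write(f"{d}\t{m}\n")


def load_gene_network(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | str = "auto",
) -> GeneNetwork:
    """Load a scored ``(gene_a, gene_b, lls)`` edge list.

    Edges are undirected and stored once; a duplicate edge keeps the last
    score seen (with a warning); self-loops are skipped with a warning.
    """
    rows = _read_rows(path, 3, delimiter, header)
    edges: dict[frozenset, float] = {}
    for lineno, fields in rows:
        ga, gb = fields[0], fields[1]
        try:
            s = float(fields[2])
        except ValueError as exc:
            raise DataFormatError(
                f"{path}: line {lineno}: non-numeric score {fields[2]!r}"
            ) from exc
        if ga == gb:
            warnings.warn(f"{path}: line {lineno}: self-loop ({ga}) skipped")
            continue
        key = frozenset((ga, gb))
        if key in edges:
            warnings.warn(
                f"{path}: line {lineno}: duplicate edge ({ga}, {gb}); keeping last score"
            )
        edges[key] = s
    if not edges:
        raise DataFormatError(f"{path}: no usable gene edges")
    return GeneNetwork(edges)


def write_gene_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlls\n")
        for e in sorted(net.edges, key=sorted):
            ga, gb = sorted(e)
            fh.write(f"{ga}\t{gb}\t{net.edges[e]!r}\n")


def load_annotations(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | str = "auto",
) -> DiseaseGeneAnnotation:
    """Load a ``(disease, gene)`` annotation table into per-disease gene sets."""
    rows = _read_rows(path, 2, delimiter, header)
    sets: dict[str, set] = {}
    for _, (d, g, *_rest) in rows:
        sets.setdefault(d, set()).add(g)
    return DiseaseGeneAnnotation({d: frozenset(g) for d, g in sets.items()})


def write_annotations(ann: DiseaseGeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tgene\n")
        for d in ann.gene_sets:
            for g in sorted(ann.gene_sets[d]):
                fh.write(f"{d}\t{g}\n")


def load_dag(
    path: str | Path,
    nodes: Iterable[str] | None = None,
    delimiter: str | None = None,
    header: bool | str = "auto",
) -> DiseaseDAG:
    """Load a ``(parent, child)`` edge list into an acyclic disease DAG.

    ``nodes`` optionally declares isolated diseases that carry no edges.
    """
    rows = _read_rows(path, 2, delimiter, header)
    edges = {(p, c) for _, (p, c, *_rest) in rows}
    node_list: list[str] = list(nodes) if nodes is not None else []
    for p, c in edges:
        for x in (p, c):
            if x not in node_list:
                node_list.append(x)
    return DiseaseDAG(node_list, edges)


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in sorted(dag.parent_edges):
            fh.write(f"{p}\t{c}\n")
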