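"""Scored protein-protein interaction networks and the RWR transition matrix.

The ingestion path mirrors STRING ``protein.links`` exports: whitespace
separated ``protein1 protein2 combined_score`` rows with integer confidence
scores, optionally prefixed by a taxon ID (``9606.``).  Confidence filtering
keeps the top fraction of edges *by count* — the highest-scoring
``ceil(fraction * |E|)`` edges, with every edge tied at the cutoff score
retained so the result is independent of input order.

Propagation uses the column-normalized adjacency: entry (i, j) is the
probability of stepping to node i from node j.  Columns of isolated nodes sum
to zero and are flagged; the walker handles them by teleporting to the
restart distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .identifiers import GeneId, IdMapTable

__all__ = [
    "PPINetwork",
    "TransitionMatrix",
    "read_edge_list",
    "filter_top_fraction",
    "build_transition_matrix",
    "write_edge_list",
]

Edge = tuple[int, int]  # (entrez_a, entrez_b) with a < b


@dataclass
class PPINetwork:
    """Undirected simple graph over genes with per-edge confidence scores."""

    nodes: list[GeneId]
    edges: dict[Edge, float]
    report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self._index = {g.entrez: i for i, g in enumerate(self.nodes)}
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a},{b}) references unknown node")

    @property
    def node_index(self) -> dict[int, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: GeneId) -> bool:
        return gene.entrez in self._index

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[self._index[a]] += 1
            deg[self._index[b]] += 1
        return deg

    def adjacency_sets(self) -> dict[int, set[int]]:
        """Entrez -> neighbor-entrez sets, built once and cached."""
        if not hasattr(self, "_adj"):
            adj: dict[int, set[int]] = {g.entrez: set() for g in self.nodes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def neighbors(self, gene: GeneId) -> set[int]:
        return self.adjacency_sets()[gene.entrez]

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency in node order."""
        n = self.n_nodes
        A = np.zeros((n, n))
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            A[i, j] = A[j, i] = 1.0
        return A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene in self.nodes:
            g.add_node(gene.entrez, symbol=gene.symbol or "")
        for (a, b), score in self.edges.items():
            g.add_edge(a, b, score=score)
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[GeneId, GeneId, float]],
        extra_nodes: Iterable[GeneId] = (),
        report: dict | None = None,
    ) -> "PPINetwork":
        """Build from (gene, gene, score) triples, collapsing duplicates.

        Symmetric duplicates keep the maximum score; self-loops are dropped
        and tallied.
        """
        node_map: dict[int, GeneId] = {}
        edge_map: dict[Edge, float] = {}
        self_loops = 0
        for u, v, score in edges:
            if u.entrez == v.entrez:
                self_loops += 1
                continue
            node_map.setdefault(u.entrez, u)
            node_map.setdefault(v.entrez, v)
            key = (min(u.entrez, v.entrez), max(u.entrez, v.entrez))
            prior = edge_map.get(key)
            edge_map[key] = score if prior is None else max(prior, score)
        for g in extra_nodes:
            node_map.setdefault(g.entrez, g)
        nodes = [node_map[e] for e in sorted(node_map)]
        rep = dict(report or {})
        rep.setdefault("self_loops_dropped", 0)
        rep["self_loops_dropped"] += self_loops
        return cls(nodes=nodes, edges=edge_map, report=rep)


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix over a fixed node order."""

    matrix: np.ndarray
    nodes: list[GeneId]
    column_sums: np.ndarray
    dangling: np.ndarray  # boolean mask of isolated-node columns

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def read_edge_list(
    path: str | Path,
    dialect: str = "string-links",
    id_map: IdMapTable | None = None,
    strip_species_prefix: bool = True,
) -> PPINetwork:
    """Read a scored edge list in STRING-links or generic-TSV dialect.

    STRING-links: whitespace-separated with header
    ``protein1 protein2 combined_score``.  Generic: tab-separated, header
    ``node1 node2 score``.  Endpoint identifiers are resolved through
    ``id_map`` when given; edges with an unmappable endpoint are dropped and
    tallied.  A non-numeric score is a hard error naming the line.
    """
    if dialect == "string-links":
        splitter = None  # any whitespace
        expected = ("protein1", "protein2", "combined_score")
    elif dialect == "generic-tsv":
        splitter = "\t"
        expected = ("node1", "node2", "score")
    else:
        raise ValueError(f"unknown edge-list dialect {dialect!r}")

    triples: list[tuple[GeneId, GeneId, float]] = []
    unmapped_edges = 0
    with open(path) as fh:
        header = fh.readline().split(splitter)
        header = [h.strip() for h in header]
        if [h.lower() for h in header[:3]] != list(expected):
            raise ValueError(
                f"{path}: expected header {expected}, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split(splitter)
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw_score = (p.strip() for p in parts[:3])
            try:
                score = float(raw_score)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {raw_score!r}"
                ) from None
            if strip_species_prefix:
                a = a.split(".", 1)[-1]
                b = b.split(".", 1)[-1]
            ga = _resolve_node(a, id_map)
            gb = _resolve_node(b, id_map)
            if ga is None or gb is None:
                unmapped_edges += 1
                continue
            triples.append((ga, gb, score))

    return PPINetwork.from_edges(
        triples, report={"unmapped_edges": unmapped_edges}
    )


def _resolve_node(token: str, id_map: IdMapTable | None) -> GeneId | None:
    if id_map is not None:
        hit = id_map.get(token)
        if hit is not None:
            return hit
    try:
        return GeneId(entrez=int(token))
    except ValueError:
        return None


def filter_top_fraction(net: PPINetwork, fraction: float) -> PPINetwork:
    """Keep the highest-confidence ``ceil(fraction * |E|)`` edges.

    Ties at the cutoff score are all retained, so the result may slightly
    exceed the ceiling.  Nodes left without edges are removed.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if net.n_edges == 0:
        raise ValueError("network has no edges to filter")
    k = math.ceil(fraction * net.n_edges)
    scores = sorted(net.edges.values(), reverse=True)
    cutoff = scores[k - 1]
    kept = {e: s for e, s in net.edges.items() if s >= cutoff}
    keep_entrez = {a for a, _ in kept} | {b for _, b in kept}
    by_entrez = {g.entrez: g for g in net.nodes}
    nodes = [by_entrez[e] for e in sorted(keep_entrez)]
    report = dict(net.report)
    report["filter_fraction"] = fraction
    report["filter_cutoff_score"] = cutoff
    return PPINetwork(nodes=nodes, edges=kept, report=report)


def build_transition_matrix(
    net: PPINetwork, weighting: str = "binary"
) -> TransitionMatrix:
    """Column-normalize the (binary or score-weighted) adjacency.

    The matrix is symmetric before normalization only; afterwards column j
    holds the step distribution out of node j.  Isolated-node columns are all
    zero and flagged in ``dangling``.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if weighting not in ("binary", "score"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = net.n_nodes
    W = np.zeros((n, n))
    for (a, b), score in net.edges.items():
        w = 1.0 if weighting == "binary" else float(score)
        i, j = net.node_index[a], net.node_index[b]
        W[i, j] = W[j, i] = w
    col = W.sum(axis=0)
    dangling = col == 0
    safe = np.where(dangling, 1.0, col)
    A = W / safe
    return TransitionMatrix(
        matrix=A, nodes=list(net.nodes), column_sums=A.sum(axis=0), dangling=dangling
    )


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network as a generic 3-column TSV (symbols when known)."""
    by_entrez = {g.entrez: g for g in net.nodes}
    rows = [
        (str(by_entrez[a]), str(by_entrez[b]), score)
        for (a, b), score in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "score"]).to_csv(
        path, sep="\t", index=False
    )
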