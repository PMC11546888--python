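"""Subnetwork extraction, centrality, hub calling and overlay export.

Hub analysis runs on the subnetwork induced by a gene set of interest
(typically seeds plus boosted genes): node degree and eigenvector centrality
— the principal eigenvector of the binary adjacency, nonnegative and
normalized to unit Euclidean norm — identify the most connected genes.  On a
disconnected graph the principal eigenvector concentrates on the dominant
component; the report flags this rather than splitting components.

The overlay network adds the differentially expressed miRNAs on top of the
boosted-gene PPI subnetwork, with typed edges (``ppi`` vs ``mirna_target``)
and a three-way gene classing (seed / boosted_target / boosted) for
visualization, exported as GraphML or node-link JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .identifiers import GeneId, MirnaId
from .interactions import TargetDatabase
from .ppi_network import PPINetwork
from .propagation import BoostedGeneSet, SeedSet

__all__ = [
    "CentralityReport",
    "OverlayNetwork",
    "induced_subnetwork",
    "degree_report",
    "eigenvector_centrality",
    "find_hubs",
    "build_overlay",
    "export_graph",
    "read_graph",
    "write_centrality_table",
]

log = logging.getLogger(__name__)


@dataclass
class CentralityReport:
    nodes: list[GeneId]
    degree: np.ndarray
    eigenvector_centrality: np.ndarray
    mean_degree: float
    mean_centrality: float
    converged: bool = True
    connected: bool = True


@dataclass
class OverlayNetwork:
    """Gene + miRNA visualization network with typed nodes and edges."""

    gene_classes: dict[int, str]  # entrez -> seed | boosted_target | boosted
    gene_symbols: dict[int, str]
    mirna_nodes: list[str]
    ppi_edges: list[tuple[int, int]]
    mirna_edges: list[tuple[str, int]]
    scores: dict[int, float] = field(default_factory=dict)


def induced_subnetwork(net: PPINetwork, genes: set[GeneId]) -> PPINetwork:
    """Subgraph on ``genes`` ∩ nodes; edges with both endpoints kept."""
    keep = {g.entrez for g in genes} & set(net.node_index)
    by_entrez = {g.entrez: g for g in net.nodes}
    nodes = [by_entrez[e] for e in sorted(keep)]
    edges = {
        (a, b): s for (a, b), s in net.edges.items() if a in keep and b in keep
    }
    return PPINetwork(nodes=nodes, edges=edges)


def degree_report(net: PPINetwork) -> tuple[dict[int, int], float]:
    """Per-node incident-edge counts and their mean."""
    deg = net.degree()
    per_node = {g.entrez: int(d) for g, d in zip(net.nodes, deg)}
    mean = float(deg.mean()) if net.n_nodes else 0.0
    return per_node, mean


def eigenvector_centrality(
    net: PPINetwork, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityReport:
    """Principal eigenvector of the binary adjacency by power iteration.

    Starts from the uniform vector (deterministic); the result is
    nonnegative with unit Euclidean norm.  Non-convergence returns the last
    iterate, flagged.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    A = net.adjacency()
    n = net.n_nodes
    x = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    for _ in range(max_iter):
        # Shifted iteration (A + I): same principal eigenvector, but immune
        # to the +/-lambda oscillation on bipartite graphs (stars, paths).
        y = A @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - impossible with >=1 edge and uniform start
            break
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            converged = True
            break
        x = y
    if not converged:
        log.warning("eigenvector centrality did not converge in %d iterations", max_iter)

    g = net.to_networkx()
    connected = nx.is_connected(g) if net.n_nodes else True
    if not connected:
        log.warning(
            "network is disconnected; centrality mass concentrates on the "
            "dominant component"
        )
    deg = net.degree()
    return CentralityReport(
        nodes=list(net.nodes),
        degree=deg,
        eigenvector_centrality=x,
        mean_degree=float(deg.mean()),
        mean_centrality=float(x.mean()),
        converged=converged,
        connected=connected,
    )


def find_hubs(
    report: CentralityReport, method: str = "degree_top_k", param: float = 3
) -> list[GeneId]:
    """Call hub genes from a centrality report.

    ``degree_top_k``: the k highest-degree nodes (ascending-Entrez
    tie-break).  ``degree_sd``: nodes whose degree strictly exceeds
    mean + param * SD (strict, so regular graphs have no outliers).
    """
    ranked = sorted(
        zip(report.nodes, report.degree), key=lambda nd: (-nd[1], nd[0].entrez)
    )
    if method == "degree_top_k":
        k = int(param)
        if k > len(ranked):
            log.warning("k=%d exceeds node count %d; returning all", k, len(ranked))
            k = len(ranked)
        return [g for g, _ in ranked[:k]]
    if method == "degree_sd":
        deg = report.degree
        cut = deg.mean() + float(param) * deg.std()
        return [g for g, d in ranked if d > cut]
    raise ValueError(f"unknown hub method {method!r}")


def build_overlay(
    boosted: BoostedGeneSet,
    seeds: SeedSet,
    db: TargetDatabase,
    ders: list[MirnaId],
    net: PPINetwork,
    degs: set[GeneId] | None = None,
    scores: dict[int, float] | None = None,
) -> OverlayNetwork:
    """Overlay the DER miRNAs on the boosted-gene PPI subnetwork.

    Gene classes are mutually exclusive: ``seed``; ``boosted_target`` — a
    non-seed boosted gene that is a DER target or a DEG; ``boosted`` —
    neither.  Only miRNAs with at least one target among the gene nodes
    appear.
    """
    der_names = {m.name for m in ders}
    gene_entrez = boosted.entrez
    seed_entrez = seeds.entrez
    deg_entrez = {g.entrez for g in degs} if degs else set()

    der_target_edges: list[tuple[str, int]] = []
    der_target_entrez: set[int] = set()
    for ia in db.interactions:
        if ia.mirna.name in der_names and ia.gene.entrez in gene_entrez:
            der_target_edges.append((ia.mirna.name, ia.gene.entrez))
            der_target_entrez.add(ia.gene.entrez)

    classes: dict[int, str] = {}
    symbols: dict[int, str] = {}
    for g in boosted.genes:
        if g.entrez in seed_entrez:
            classes[g.entrez] = "seed"
        elif g.entrez in der_target_entrez or g.entrez in deg_entrez:
            classes[g.entrez] = "boosted_target"
        else:
            classes[g.entrez] = "boosted"
        symbols[g.entrez] = g.symbol or str(g.entrez)

    sub = induced_subnetwork(net, set(boosted.genes))
    ppi_edges = sorted(sub.edges)
    mirna_nodes = sorted({m for m, _ in der_target_edges})
    return OverlayNetwork(
        gene_classes=classes,
        gene_symbols=symbols,
        mirna_nodes=mirna_nodes,
        ppi_edges=ppi_edges,
        mirna_edges=sorted(der_target_edges),
        scores=dict(scores or {}),
    )


def _overlay_to_networkx(overlay: OverlayNetwork) -> nx.Graph:
    g = nx.Graph()
    deg_count: dict = {}
    for a, b in overlay.ppi_edges:
        deg_count[a] = deg_count.get(a, 0) + 1
        deg_count[b] = deg_count.get(b, 0) + 1
    for entrez, cls in overlay.gene_classes.items():
        g.add_node(
            f"gene:{entrez}",
            node_type="gene",
            cls=cls,
            symbol=overlay.gene_symbols.get(entrez, str(entrez)),
            score=float(overlay.scores.get(entrez, 0.0)),
            degree=int(deg_count.get(entrez, 0)),
        )
    for name in overlay.mirna_nodes:
        g.add_node(f"mirna:{name}", node_type="mirna", cls="mirna",
                   symbol=name, score=0.0, degree=0)
    for a, b in overlay.ppi_edges:
        g.add_edge(f"gene:{a}", f"gene:{b}", edge_type="ppi")
    for m, t in overlay.mirna_edges:
        g.add_edge(f"mirna:{m}", f"gene:{t}", edge_type="mirna_target")
    return g


def export_graph(overlay: OverlayNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the overlay as GraphML or node-link JSON (round-trip safe)."""
    g = _overlay_to_networkx(overlay)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "json":
        data = nx.node_link_data(g, edges="links")
        path.write_text(json.dumps(data, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> OverlayNetwork:
    """Read an overlay previously written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "json":
        g = nx.node_link_graph(json.loads(path.read_text()), edges="links")
    else:
        raise ValueError(f"unknown export format {format!r}")

    classes: dict[int, str] = {}
    symbols: dict[int, str] = {}
    scores: dict[int, float] = {}
    mirna_nodes: list[str] = []
    for node, attrs in g.nodes(data=True):
        if attrs["node_type"] == "gene":
            entrez = int(str(node).split(":", 1)[1])
            classes[entrez] = attrs["cls"]
            symbols[entrez] = attrs["symbol"]
            if attrs.get("score"):
                scores[entrez] = float(attrs["score"])
        else:
            mirna_nodes.append(str(node).split(":", 1)[1])
    ppi_edges = []
    mirna_edges = []
    for u, v, attrs in g.edges(data=True):
        if attrs["edge_type"] == "ppi":
            a, b = int(str(u).split(":", 1)[1]), int(str(v).split(":", 1)[1])
            ppi_edges.append((min(a, b), max(a, b)))
        else:
            m, t = (u, v) if str(u).startswith("mirna:") else (v, u)
            mirna_edges.append(
                (str(m).split(":", 1)[1], int(str(t).split(":", 1)[1]))
            )
    return OverlayNetwork(
        gene_classes=classes,
        gene_symbols=symbols,
        mirna_nodes=sorted(mirna_nodes),
        ppi_edges=sorted(ppi_edges),
        mirna_edges=sorted(mirna_edges),
        scores=scores,
    )


def write_centrality_table(report: CentralityReport, path: str | Path) -> None:
    pd.DataFrame(
        {
            "entrez": [g.entrez for g in report.nodes],
            "symbol": [g.symbol or "" for g in report.nodes],
            "degree": report.degree,
            "eigenvector_centrality": report.eigenvector_centrality,
        }
    ).to_csv(path, sep="\t", index=False)
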