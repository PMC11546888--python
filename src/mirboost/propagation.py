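"""Seed construction, random walk with restart, and boosted gene sets.

The walker starts on the seed genes (by default the intersection of the
differentially expressed genes and the targets of differentially expressed
miRNAs, restricted to the network) and at each step either moves to a random
neighbor with probability ``1 - p`` or restarts on the seeds with probability
``p``:

    u <- (1 - p) * A @ u + p * u0

where ``A`` is the column-normalized adjacency and ``u0`` the restart
distribution, uniform over seeds.  The fixed point is the stationary
proximity of every node to the seed set (its "distance score"); it equals the
direct linear solve ``u* = p (I - (1-p) A)^-1 u0``.  Mass that would vanish
into isolated (zero-column) nodes is redirected to the restart distribution
each step, so the iterate stays a probability distribution exactly.

A boosted gene set at level ``q`` is the seeds plus the top
``ceil(q * n_nonseed)`` non-seed nodes by stationary score, with ties broken
by ascending Entrez ID for reproducibility.  Non-seed members are classified
``direct`` when one hop from a seed, else ``indirect``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .identifiers import GeneId
from .ppi_network import PPINetwork, TransitionMatrix

__all__ = [
    "SeedSet",
    "RWRScores",
    "BoostedGeneSet",
    "construct_seed_set",
    "make_restart_vector",
    "rwr",
    "select_boosted",
    "classify_connectivity",
]

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Seed genes restricted to network nodes, with provenance flags."""

    genes: set[GeneId]
    provenance: dict[int, dict[str, bool]]  # entrez -> {is_DEG, is_DER_target}
    dropped: list[GeneId]  # requested but absent from the network

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def entrez(self) -> set[int]:
        return {g.entrez for g in self.genes}


@dataclass
class RWRScores:
    """Stationary node probabilities of the restart walk."""

    scores: np.ndarray  # aligned with nodes
    nodes: list[GeneId]
    restart_p: float
    iterations: int
    converged: bool

    def by_entrez(self) -> dict[int, float]:
        return {g.entrez: float(s) for g, s in zip(self.nodes, self.scores)}


@dataclass
class BoostedGeneSet:
    """Seeds plus top-ranked propagated genes at one boosting level."""

    level: float
    genes: list[GeneId]  # seeds first, then non-seeds by descending score
    classification: dict[int, str] = field(default_factory=dict)  # non-seed entrez -> direct|indirect

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def entrez(self) -> set[int]:
        return {g.entrez for g in self.genes}


def construct_seed_set(
    degs: set[GeneId],
    der_targets: set[GeneId],
    net: PPINetwork,
    mode: str = "intersection",
) -> SeedSet:
    """Intersect (or union) the DEG and DER-target sets and keep network members.

    An empty result is a hard error: propagation from nothing is undefined.
    """
    if mode == "intersection":
        wanted = degs & der_targets
    elif mode == "union":
        wanted = degs | der_targets
    else:
        raise ValueError(f"unknown seed mode {mode!r}")
    genes = {g for g in wanted if g in net}
    dropped = sorted((g for g in wanted if g not in net), key=lambda g: g.entrez)
    if not genes:
        raise ValueError(
            f"seed set is empty after network restriction "
            f"({len(dropped)} candidate(s) absent from the network)"
        )
    provenance = {
        g.entrez: {"is_DEG": g in degs, "is_DER_target": g in der_targets}
        for g in genes
    }
    return SeedSet(genes=genes, provenance=provenance, dropped=dropped)


def make_restart_vector(seeds: SeedSet, net: PPINetwork) -> np.ndarray:
    """Restart distribution: uniform mass 1/|seeds| on each seed node."""
    if not seeds.genes:
        raise ValueError("seed set is empty")
    u0 = np.zeros(net.n_nodes)
    for g in seeds.genes:
        u0[net.node_index[g.entrez]] = 1.0
    return u0 / u0.sum()


def rwr(
    A: TransitionMatrix,
    u0: np.ndarray,
    restart_p: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> RWRScores:
    """Iterate the restart walk to its fixed point.

    Dangling (isolated-node) columns transmit no mass; the shortfall is
    teleported to ``u0`` so every iterate sums to one.  Convergence is an L1
    change below ``tol``.
    """
    if not 0 < restart_p <= 1:
        raise ValueError(f"restart_p must be in (0, 1], got {restart_p}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if abs(u0.sum() - 1.0) > 1e-9:
        raise ValueError("u0 must sum to 1")

    if restart_p == 1.0:
        return RWRScores(
            scores=u0.copy(), nodes=list(A.nodes), restart_p=restart_p,
            iterations=1, converged=True,
        )

    u = u0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        stepped = A.matrix @ u
        lost = float(u[A.dangling].sum()) if A.dangling.any() else 0.0
        u_new = (1.0 - restart_p) * (stepped + lost * u0) + restart_p * u0
        delta = float(np.abs(u_new - u).sum())
        u = u_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("RWR did not converge in %d iterations", max_iter)
    return RWRScores(
        scores=u, nodes=list(A.nodes), restart_p=restart_p,
        iterations=iterations, converged=converged,
    )


def select_boosted(
    scores: RWRScores,
    seeds: SeedSet,
    level: float,
    net: PPINetwork,
) -> BoostedGeneSet:
    """Extract the boosted set at a boosting level in [0, 1].

    The level is a fraction of the non-seed node pool: the result is the
    seeds plus the ``ceil(level * (n_nodes - n_seeds))`` highest-scoring
    non-seeds.  Ranking is by descending score with ascending-Entrez
    tie-break, so the cut is deterministic.
    """
    if not 0 <= level <= 1:
        raise ValueError(f"boosting level must be in [0, 1], got {level}")
    seed_entrez = seeds.entrez
    seed_genes = sorted(seeds.genes, key=lambda g: g.entrez)
    nonseeds = [
        (g, float(s)) for g, s in zip(scores.nodes, scores.scores)
        if g.entrez not in seed_entrez
    ]
    nonseeds.sort(key=lambda gs: (-gs[1], gs[0].entrez))
    k = math.ceil(level * len(nonseeds))
    chosen = [g for g, _ in nonseeds[:k]]

    adj = net.adjacency_sets()
    classification = {
        g.entrez: "direct" if adj.get(g.entrez, set()) & seed_entrez else "indirect"
        for g in chosen
    }
    return BoostedGeneSet(
        level=level, genes=seed_genes + chosen, classification=classification
    )


def classify_connectivity(
    boosted: BoostedGeneSet, seeds: SeedSet, net: PPINetwork
) -> tuple[int, int]:
    """Count (direct, indirect) non-seed boosted genes.

    Direct means one-hop adjacency to at least one seed.
    """
    adj = net.adjacency_sets()
    seed_entrez = seeds.entrez
    n_direct = n_indirect = 0
    for g in boosted.genes:
        if g.entrez in seed_entrez:
            continue
        if adj.get(g.entrez, set()) & seed_entrez:
            n_direct += 1
        else:
            n_indirect += 1
    return n_direct, n_indirect
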