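"""Shared fixtures: tiny hand-built networks, ID maps and collections."""

from __future__ import annotations

import numpy as np
import pytest

from mirboost.identifiers import GeneId, IdMapTable
from mirboost.ppi_network import PPINetwork


def gid(entrez: int, symbol: str | None = None) -> GeneId:
    return GeneId(entrez=entrez, symbol=symbol)


def make_net(edges, extra_nodes=(), scores=None) -> PPINetwork:
    """Network from (a, b) entrez pairs; score 1.0 unless given per-edge."""
    triples = []
    for i, (a, b) in enumerate(edges):
        s = 1.0 if scores is None else float(scores[i])
        triples.append((gid(a), gid(b), s))
    return PPINetwork.from_edges(triples, extra_nodes=[gid(e) for e in extra_nodes])


def random_net(rng: np.random.Generator, n_max: int = 50) -> PPINetwork:
    """Random connected-ish simple graph for oracle sweeps."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.08, 0.4))
    edges = []
    for i in range(1, n):  # random tree keeps things connected
        j = int(rng.integers(0, i))
        edges.append((i + 1, j + 1))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((j + 1, i + 1))
    return make_net(edges)


@pytest.fixture
def id_map() -> IdMapTable:
    return IdMapTable(
        [
            ("SMAD3", ["MADH3"], 4088),
            ("HRAS", [], 3265),
            ("MAPK8", ["JNK1"], 5599),
            ("YAP1", [], 10413),
        ]
    )


@pytest.fixture
def path_abc() -> PPINetwork:
    """Path graph a(1) - b(2) - c(3)."""
    return make_net([(1, 2), (2, 3)])


@pytest.fixture
def triangle() -> PPINetwork:
    return make_net([(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def star6() -> PPINetwork:
    """Star: hub 1 with five leaves 2..6."""
    return make_net([(1, k) for k in range(2, 7)])
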