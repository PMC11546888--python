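"""Hypergeometric gene-set enrichment and the permutation null.

The enrichment statistic is the one-sided hypergeometric upper tail: with a
universe of ``N`` genes of which ``K`` belong to a term, a query of ``n``
genes and an observed overlap of ``k``, the p-value is ``P(X >= k)`` for
``X ~ Hypergeom(N, K, n)``.  Multiplicity is controlled by
Benjamini-Hochberg over every term tested; the permutation machinery counts
terms passing a *raw* p threshold, matching how enriched-pathway counts are
typically compared across boosting levels.

The permutation null draws size-matched gene sets uniformly from the
universe and records, per draw, how many terms pass the threshold.  The
empirical p-value uses the add-one estimator ``(r + 1) / (n_perm + 1)`` with
``r`` the number of null counts at least as large as the observed count, so
it is floored at ``1 / (n_perm + 1)`` — with 10,000 permutations,
``1/10001 ~= 9.999e-5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .identifiers import GeneId, IdMapTable

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "PermutationNull",
    "read_gmt",
    "hypergeom_p",
    "enrich",
    "count_enriched",
    "add_one_empirical_p",
    "permutation_null",
    "dotplot_table",
    "write_enrichment_table",
]


@dataclass
class GeneSetCollection:
    """term_id -> (description, member genes), plus the background universe."""

    terms: dict[str, tuple[str, set[GeneId]]]
    universe: set[GeneId]
    report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")
            if not members <= self.universe:
                raise ValueError(f"term {tid!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.terms)

    def restrict_universe(self, universe: set[GeneId]) -> "GeneSetCollection":
        """Re-background the collection (e.g. onto the PPI node set)."""
        terms = {
            tid: (desc, members & universe)
            for tid, (desc, members) in self.terms.items()
        }
        terms = {tid: tm for tid, tm in terms.items() if tm[1]}
        return GeneSetCollection(terms=terms, universe=set(universe))


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    description: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float


@dataclass
class PermutationNull:
    """Null distribution of enriched-term counts over random gene sets."""

    n_perm: int
    null_counts: list[int]
    observed: int
    empirical_p: float
    rng_seed: int


def read_gmt(path: str | Path, id_map: IdMapTable) -> GeneSetCollection:
    """Read a standard GMT file (term, description, members; tab-separated).

    Members are mapped through ``id_map``; unmappable members are dropped and
    tallied.  The universe defaults to the union of all mapped members.
    """
    terms: dict[str, tuple[str, set[GeneId]]] = {}
    unmapped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, desc, *raw_members = fields
            members: set[GeneId] = set()
            for token in raw_members:
                token = token.strip()
                if not token:
                    continue
                gid = id_map.get(token)
                if gid is None:
                    try:
                        gid = GeneId(entrez=int(token), symbol=id_map.symbol_of(int(token)))
                    except ValueError:
                        unmapped += 1
                        continue
                members.add(gid)
            if members:
                terms[term_id] = (desc, members)
    universe = set().union(*(m for _, m in terms.values())) if terms else set()
    return GeneSetCollection(
        terms=terms, universe=universe, report={"unmapped_members": unmapped}
    )


def hypergeom_p(overlap: int, term_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    k, K, n, N = overlap, term_size, query_size, universe_size
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[GeneId],
    coll: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 1,
) -> list[EnrichmentRecord]:
    """Test the query against every term in the collection.

    Query genes outside the universe are dropped (tallied via the returned
    records' ``query_size``); BH adjustment spans all tested terms, then
    records with overlap below ``min_overlap`` are omitted.  Output is
    sorted by ascending p-value with term-id tie-break.
    """
    restricted = query & coll.universe
    if not restricted:
        raise ValueError("query is empty after restriction to the universe")
    N = len(coll.universe)
    n = len(restricted)
    term_ids = sorted(coll.terms)
    raw_p = np.empty(len(term_ids))
    overlaps = np.empty(len(term_ids), dtype=int)
    for i, tid in enumerate(term_ids):
        _, members = coll.terms[tid]
        k = len(restricted & members)
        overlaps[i] = k
        raw_p[i] = hypergeom_p(k, len(members), n, N)
    _, adj_p, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")

    records = [
        EnrichmentRecord(
            term_id=tid,
            description=coll.terms[tid][0],
            overlap=int(overlaps[i]),
            term_size=len(coll.terms[tid][1]),
            query_size=n,
            universe_size=N,
            p_value=float(raw_p[i]),
            p_adjusted=float(adj_p[i]),
        )
        for i, tid in enumerate(term_ids)
        if overlaps[i] >= min_overlap
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def count_enriched(
    records: Sequence[EnrichmentRecord],
    threshold: float = 0.01,
    use_adjusted: bool = False,
) -> int:
    """Count records passing the significance threshold (strict <)."""
    return sum(
        1
        for r in records
        if (r.p_adjusted if use_adjusted else r.p_value) < threshold
    )


def add_one_empirical_p(null_counts: Sequence[int], observed: int) -> float:
    """Add-one permutation p: (r + 1) / (n + 1), r = #{null >= observed}."""
    r = sum(1 for c in null_counts if c >= observed)
    return (r + 1) / (len(null_counts) + 1)


def permutation_null(
    coll: GeneSetCollection,
    set_size: int,
    n_perm: int,
    threshold: float,
    observed: int,
    rng_seed: int,
    min_overlap: int = 1,
) -> PermutationNull:
    """Size-matched uniform permutation null for the enriched-term count.

    Each permutation draws ``set_size`` genes from the universe without
    replacement and counts terms passing the raw-p threshold exactly as the
    observed analysis did.
    """
    if set_size > len(coll.universe):
        raise ValueError("set_size exceeds the universe")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng_seed)
    universe = sorted(coll.universe, key=lambda g: g.entrez)

    # Flat arrays for speed: membership tested by index sets per term.
    idx_of = {g: i for i, g in enumerate(universe)}
    term_ids = sorted(coll.terms)
    term_idx = [
        np.array(sorted(idx_of[g] for g in coll.terms[tid][1]), dtype=np.intp)
        for tid in term_ids
    ]
    term_sizes = np.array([len(t) for t in term_idx])
    N = len(universe)

    null_counts: list[int] = []
    member_mask = np.zeros(N, dtype=bool)
    for _ in range(n_perm):
        draw = rng.choice(N, size=set_size, replace=False)
        member_mask[:] = False
        member_mask[draw] = True
        ks = np.array([int(member_mask[t].sum()) for t in term_idx])
        # Vectorized upper tail; k=0 forced to p=1 to match hypergeom_p.
        p = hypergeom.sf(ks - 1, N, term_sizes, set_size)
        p = np.where(ks == 0, 1.0, p)
        null_counts.append(int(((ks >= min_overlap) & (p < threshold)).sum()))

    return PermutationNull(
        n_perm=n_perm,
        null_counts=null_counts,
        observed=observed,
        empirical_p=add_one_empirical_p(null_counts, observed),
        rng_seed=rng_seed,
    )


def dotplot_table(
    per_level_records: Mapping[float, Sequence[EnrichmentRecord]],
    terms: Sequence[str],
) -> pd.DataFrame:
    """Long-format (term, level, overlap, p_value) table for dot plots.

    A term absent (non-significant) at a level emits the row with missing
    overlap/p — the tabular "N/A" convention.
    """
    rows = []
    for level in sorted(per_level_records):
        by_term = {r.term_id: r for r in per_level_records[level]}
        for tid in terms:
            rec = by_term.get(tid)
            if rec is None:
                rows.append((tid, level, pd.NA, pd.NA))
            else:
                rows.append((tid, level, rec.overlap, rec.p_value))
    return pd.DataFrame(rows, columns=["term", "level", "overlap", "p_value"])


def write_enrichment_table(
    records: Sequence[EnrichmentRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (
                r.term_id, r.description, r.overlap, r.term_size,
                r.query_size, r.universe_size, r.p_value, r.p_adjusted,
            )
            for r in records
        ],
        columns=[
            "term_id", "description", "overlap", "term_size",
            "query_size", "universe_size", "p_value", "p_adjusted",
        ],
    ).to_csv(path, sep="\t", index=False)
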