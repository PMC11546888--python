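"""miRNA-target interaction tables: dialect-aware reading and set algebra.

Target databases disagree on column names, so each supported dialect is a
small column map (which column holds the miRNA name, which the target gene,
and whether the gene is given as a symbol or an Entrez number).  The maps are
data, not code, and can be overridden from a YAML file to track export-format
drift.  Databases combine at the (miRNA, gene) pair level — the conservative
"experimentally validated intersection" workflow and the permissive union are
both supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .identifiers import GeneId, IdMapTable, MirnaId, map_symbols, normalize_mirna

__all__ = [
    "TargetInteraction",
    "TargetDatabase",
    "BUILTIN_DIALECTS",
    "load_dialects",
    "read_target_table",
    "combine_databases",
    "targets_of",
    "write_target_table",
]


@dataclass(frozen=True)
class TargetInteraction:
    """One (miRNA, target gene) pair; the source tag is bookkeeping only."""

    mirna: MirnaId
    gene: GeneId
    source: str = field(default="", compare=False)

    @property
    def pair(self) -> tuple[str, int]:
        return (self.mirna.name, self.gene.entrez)


@dataclass
class TargetDatabase:
    """A deduplicated set of miRNA-target interactions."""

    interactions: set[TargetInteraction]
    name: str = ""
    report: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.interactions)

    def pairs(self) -> set[tuple[str, int]]:
        return {i.pair for i in self.interactions}


# Column maps emulating common export dialects.  gene_kind: symbol | entrez.
BUILTIN_DIALECTS: dict[str, dict] = {
    "generic": {"mirna": "mirna", "gene": "target", "gene_kind": "symbol"},
    "mirtarbase-like": {"mirna": "miRNA", "gene": "Target Gene", "gene_kind": "symbol"},
    "tarbase-like": {"mirna": "mirna", "gene": "geneName", "gene_kind": "symbol"},
    "targetscan-like": {"mirna": "miRNA", "gene": "Gene Symbol", "gene_kind": "symbol"},
    "mirdb-like": {"mirna": "mirna", "gene": "GeneSymbol", "gene_kind": "symbol"},
}


def load_dialects(path: str | Path | None = None) -> dict[str, dict]:
    """Built-in dialect column maps, optionally overlaid from a YAML file."""
    dialects = {k: dict(v) for k, v in BUILTIN_DIALECTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for name, cols in user.items():
            dialects[name] = dict(cols)
    return dialects


def read_target_table(
    path: str | Path,
    dialect: str | Mapping[str, str],
    id_map: IdMapTable,
    known_mirnas: Iterable[str],
    name: str | None = None,
    dialects: Mapping[str, Mapping[str, str]] | None = None,
) -> TargetDatabase:
    """Read one miRNA-target table in the given dialect.

    Each row yields zero or more interactions: the miRNA name is normalized
    (arm expansion included) and the gene mapped to Entrez; rows whose miRNA
    or gene cannot be resolved contribute nothing and are tallied in the
    database's ``report``.
    """
    if isinstance(dialect, str):
        table = dict(dialects or BUILTIN_DIALECTS)
        if dialect not in table:
            raise ValueError(f"unknown dialect {dialect!r}; have {sorted(table)}")
        colmap = table[dialect]
    else:
        colmap = dict(dialect)

    sep = colmap.get("sep", "\t")
    df = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    for role in ("mirna", "gene"):
        col = colmap[role]
        if col not in df.columns:
            raise ValueError(
                f"{path}: required column {col!r} (role {role}) not found; "
                f"columns are {list(df.columns)}"
            )

    known = set(known_mirnas)
    gene_kind = colmap.get("gene_kind", "symbol")
    dbname = name or Path(path).stem
    interactions: set[TargetInteraction] = set()
    unmapped_mirnas = 0
    unmapped_genes = 0
    for _, row in df.iterrows():
        mirnas = normalize_mirna(str(row[colmap["mirna"]]), known)
        if not mirnas:
            unmapped_mirnas += 1
            continue
        raw_gene = str(row[colmap["gene"]]).strip()
        if gene_kind == "entrez":
            try:
                gene = GeneId(entrez=int(raw_gene), symbol=id_map.symbol_of(int(raw_gene)))
            except ValueError:
                unmapped_genes += 1
                continue
        else:
            mapping, missed = map_symbols([raw_gene], id_map)
            if missed:
                unmapped_genes += 1
                continue
            gene = mapping[raw_gene]
        for m in mirnas:
            interactions.add(TargetInteraction(mirna=m, gene=gene, source=dbname))

    report = {
        "rows_in": int(len(df)),
        "interactions_out": len(interactions),
        "unmapped_mirna_rows": unmapped_mirnas,
        "unmapped_gene_rows": unmapped_genes,
    }
    return TargetDatabase(interactions=interactions, name=dbname, report=report)


def combine_databases(
    dbs: Sequence[TargetDatabase], mode: str = "intersection"
) -> TargetDatabase:
    """Combine databases at the (miRNA, gene) pair level.

    ``intersection`` keeps pairs present in every input, ``union`` pairs
    present in any, ``single`` passes the sole input through.  Combining a
    single database under ``intersection`` degenerates to identity.
    """
    if not dbs:
        raise ValueError("need at least one database")
    if mode == "single":
        if len(dbs) != 1:
            raise ValueError("mode='single' requires exactly one database")
        return dbs[0]
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combine mode {mode!r}")

    pair_sets = [db.pairs() for db in dbs]
    if mode == "intersection":
        keep = set.intersection(*pair_sets)
    else:
        keep = set.union(*pair_sets)

    # Representative interaction objects, source tags concatenated per pair.
    by_pair: dict[tuple[str, int], TargetInteraction] = {}
    sources: dict[tuple[str, int], list[str]] = {}
    for db in dbs:
        for ia in db.interactions:
            if ia.pair in keep:
                by_pair.setdefault(ia.pair, ia)
                sources.setdefault(ia.pair, [])
                if ia.source and ia.source not in sources[ia.pair]:
                    sources[ia.pair].append(ia.source)
    combined = {
        TargetInteraction(
            mirna=ia.mirna, gene=ia.gene, source="+".join(sources[pair])
        )
        for pair, ia in by_pair.items()
    }
    name = f"{mode}(" + ",".join(db.name for db in dbs) + ")"
    return TargetDatabase(interactions=combined, name=name)


def targets_of(
    db: TargetDatabase, ders: Sequence[MirnaId]
) -> tuple[set[GeneId], list[MirnaId]]:
    """Union of target genes over the listed miRNAs.

    Returns the target set plus the miRNAs that had no interaction in the
    database (reported, not an error).
    """
    by_mirna: dict[str, set[GeneId]] = {}
    for ia in db.interactions:
        by_mirna.setdefault(ia.mirna.name, set()).add(ia.gene)
    targets: set[GeneId] = set()
    missing: list[MirnaId] = []
    for m in ders:
        hits = by_mirna.get(m.name)
        if hits:
            targets |= hits
        else:
            missing.append(m)
    return targets, missing


def write_target_table(db: TargetDatabase, path: str | Path) -> None:
    """Write the canonical 3-column TSV (mirna, entrez, source)."""
    rows = sorted(
        ((ia.mirna.name, ia.gene.entrez, ia.source) for ia in db.interactions)
    )
    pd.DataFrame(rows, columns=["mirna", "entrez", "source"]).to_csv(
        path, sep="\t", index=False
    )
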