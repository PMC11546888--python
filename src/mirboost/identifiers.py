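"""Canonicalization of mature miRNA names and gene symbol -> Entrez mapping.

Mature miRNA names carry an arm suffix (``-5p``/``-3p``) denoting which arm of
the precursor hairpin the mature sequence comes from.  Input lists frequently
omit the suffix or use the legacy ``*`` (star) notation for the minor arm, so
every raw name is resolved against a dictionary of known canonical names.  A
name without an arm suffix expands to every known arm — the recall-preserving
choice, since downstream set intersections remove spurious expansions.

Gene identity is anchored on numeric Entrez IDs; symbols and aliases are
display strings resolved case-insensitively through an :class:`IdMapTable`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MirnaId",
    "GeneId",
    "IdMapTable",
    "normalize_mirna",
    "map_symbols",
    "read_known_mirnas",
]

_ARM_SUFFIXES = ("-5p", "-3p")


@dataclass(frozen=True)
class MirnaId:
    """A canonical mature miRNA name, e.g. ``hsa-miR-26b-5p``."""

    name: str
    species_prefix: str = field(compare=False)
    arm: str = field(compare=False)  # "5p", "3p" or "unspecified"

    @classmethod
    def from_name(cls, name: str) -> "MirnaId":
        prefix = name.split("-", 1)[0] if "-" in name else ""
        low = name.lower()
        if low.endswith("-5p"):
            arm = "5p"
        elif low.endswith("-3p"):
            arm = "3p"
        else:
            arm = "unspecified"
        return cls(name=name, species_prefix=prefix, arm=arm)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class GeneId:
    """A gene keyed by its Entrez ID; the symbol is display-only."""

    entrez: int
    symbol: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.entrez < 1:
            raise ValueError(f"Entrez ID must be >= 1, got {self.entrez}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol or str(self.entrez)


class IdMapTable:
    """Case-insensitive symbol/alias -> Entrez lookup table.

    Within one table a symbol or alias resolves to at most one Entrez ID;
    conflicting duplicate entries raise at construction time.
    """

    def __init__(self, records: Iterable[tuple[str, Sequence[str], int]]):
        # key (lowercased symbol or alias) -> (entrez, primary symbol)
        self._lookup: dict[str, tuple[int, str]] = {}
        self._by_entrez: dict[int, str] = {}
        for symbol, aliases, entrez in records:
            entrez = int(entrez)
            self._by_entrez.setdefault(entrez, symbol)
            for key in (symbol, *aliases):
                key = key.strip()
                if not key:
                    continue
                low = key.lower()
                prior = self._lookup.get(low)
                if prior is not None and prior[0] != entrez:
                    raise ValueError(
                        f"conflicting ID map entries for {key!r}: "
                        f"{prior[0]} vs {entrez}"
                    )
                self._lookup.setdefault(low, (entrez, symbol))
        if not self._lookup:
            raise ValueError("ID map table is empty")

    def __len__(self) -> int:
        return len(self._by_entrez)

    def get(self, symbol: str) -> GeneId | None:
        hit = self._lookup.get(symbol.strip().lower())
        if hit is None:
            return None
        entrez, primary = hit
        return GeneId(entrez=entrez, symbol=primary)

    def symbol_of(self, entrez: int) -> str | None:
        return self._by_entrez.get(entrez)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMapTable":
        """Read a TSV with header columns ``symbol``, ``aliases``, ``entrez``.

        Aliases are pipe-separated and may be empty.
        """
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"symbol", "aliases", "entrez"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(
                    f"ID map {path} missing required column(s): {sorted(missing)}"
                )
            for row in reader:
                aliases = [a for a in (row["aliases"] or "").split("|") if a]
                records.append((row["symbol"], aliases, int(row["entrez"])))
        return cls(records)


def normalize_mirna(raw_name: str, known_names: Iterable[str]) -> list[MirnaId]:
    """Resolve a raw miRNA name against a set of known canonical names.

    A name already carrying ``-5p``/``-3p`` resolves to exactly that entry (or
    nothing).  A name without an arm suffix — including legacy ``*`` names,
    whose star is stripped — expands to every known arm variant, ordered 5p
    before 3p; an exact arm-less match, if the dictionary contains one, comes
    first.  Matching is case-insensitive; returned names are the dictionary's
    canonical spellings.  An empty list (never an exception) signals "unknown";
    callers tally these.
    """
    raw = raw_name.strip()
    if not raw:
        raise ValueError("miRNA name is empty after trimming")
    lookup = {name.lower(): name for name in known_names}
    if not lookup:
        raise ValueError("known_names must be non-empty")

    low = raw.lower()
    if low.endswith(_ARM_SUFFIXES):
        hit = lookup.get(low)
        return [MirnaId.from_name(hit)] if hit else []

    if low.endswith("*"):  # legacy minor-arm star notation
        low = low[:-1]

    out: list[MirnaId] = []
    for candidate in (low, low + "-5p", low + "-3p"):
        hit = lookup.get(candidate)
        if hit is not None:
            out.append(MirnaId.from_name(hit))
    return out


def map_symbols(
    symbols: Sequence[str], table: IdMapTable
) -> tuple[dict[str, GeneId], list[str]]:
    """Map gene symbols to :class:`GeneId`, splitting hits from misses.

    Every input symbol lands in exactly one of the two outputs; aliases
    resolve to their primary record and ``unmapped`` preserves input order.
    """
    mapping: dict[str, GeneId] = {}
    unmapped: list[str] = []
    for sym in symbols:
        gid = table.get(sym)
        if gid is None:
            unmapped.append(sym)
        else:
            mapping[sym] = gid
    return mapping, unmapped


def read_known_mirnas(path: str | Path) -> set[str]:
    """Read a one-name-per-line mature miRNA dictionary (miRBase style)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
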