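"""Gene-set collections: GMT parsing, size filtering, universe handling.

A gene set (pathway) is a named group of gene symbols; a collection of them
defines the universe of genes eligible for enrichment testing.  Gene identity
is an exact, case-sensitive string match — no symbol aliasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "restrict_to_measured",
]

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """Raised for a malformed GMT line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GMT line {lineno}: {message}")


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: unique id, free-text description, member gene symbols."""

    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} has no member genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered list of gene sets with unique ids.

    The ``universe`` is always exactly the union of member genes; it is
    recomputed by every operation that changes membership.
    """

    sets: tuple[GeneSet, ...]
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [gs.id for gs in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene set ids: {dupes}")
        union: set[str] = set()
        for gs in self.sets:
            union |= gs.genes
        object.__setattr__(self, "universe", frozenset(union))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for gs in self.sets:
            if gs.id == set_id:
                return gs
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [gs.id for gs in self.sets]

    def filter_by_size(self, min_size: int, max_size: int) -> "GeneSetCollection":
        return filter_by_size(self, min_size, max_size)

    def restrict_to_measured(self, measured: Iterable[str]) -> "GeneSetCollection":
        return restrict_to_measured(self, measured)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, gene symbols...).

    Duplicate gene symbols within a line are collapsed.  Lines with fewer than
    three fields raise :class:`GmtParseError` naming the line number;
    duplicate set ids raise ``ValueError``.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    lineno, f"expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GmtParseError(lineno, f"gene set {set_id!r} has no genes")
            sets.append(GeneSet(id=set_id, name=name, genes=genes))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (member genes in sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.id, gs.name, *sorted(gs.genes)]) + "\n")


def filter_by_size(
    coll: GeneSetCollection, min_size: int, max_size: int
) -> GeneSetCollection:
    """Retain sets with ``min_size <= |genes| <= max_size`` (inclusive).

    The conventional range for curated pathway databases is 20–400 genes,
    which drops tiny sets (unstable statistics) and very broad ones (weak
    biological specificity).
    """
    if not 1 <= min_size <= max_size:
        raise ValueError(
            f"require 1 <= min_size <= max_size, got ({min_size}, {max_size})"
        )
    kept = tuple(gs for gs in coll.sets if min_size <= len(gs) <= max_size)
    return GeneSetCollection(sets=kept)


def restrict_to_measured(
    coll: GeneSetCollection, measured: Iterable[str]
) -> GeneSetCollection:
    """Intersect each set with the measured genes; drop sets that become empty.

    Callers who want a size filter on the restricted sets must re-apply it.
    """
    measured = frozenset(measured)
    if not measured:
        raise ValueError("measured gene set must be non-empty")
    kept: list[GeneSet] = []
    dropped: list[str] = []
    for gs in coll.sets:
        genes = gs.genes & measured
        if genes:
            kept.append(GeneSet(id=gs.id, name=gs.name, genes=genes))
        else:
            dropped.append(gs.id)
    if dropped:
        logger.warning(
            "restrict_to_measured dropped %d set(s) with no measured genes: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return GeneSetCollection(sets=tuple(kept))
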