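"""The queryable index over a collection of gene sets.

A :class:`CollectionIndex` holds, for one analysis collection: the
member gene sets, an inverted gene → set_id map, per-gene document
frequencies (df), and the gene universe. Two quantities of the
enrichment model live here: ``m`` (the number of networks in the
collection, the BH multiplicity) and ``N`` (the universe size, the
hypergeometric population). Different analysis collections are simply
different index instances, each with its own universe.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from .cx import GeneSet
from .errors import EmptyCollectionError, IndexFormatError

__all__ = [
    "CollectionIndex",
    "build_index",
    "candidate_networks",
    "save_index",
    "load_index",
]

_HEADER = "#netquery-index\tv1"


@dataclass
class CollectionIndex:
    networks: dict[str, GeneSet]
    gene_to_sets: dict[str, tuple[str, ...]] = field(repr=False)
    df: dict[str, int] = field(repr=False)
    universe: frozenset[str] = field(repr=False)

    @property
    def m(self) -> int:
        """Number of networks in the collection (BH multiplicity)."""
        return len(self.networks)

    @property
    def N(self) -> int:
        """Number of unique genes across all member sets (population size)."""
        return len(self.universe)


def build_index(
    collection: Iterable[GeneSet], min_set_size: int = 1
) -> CollectionIndex:
    """Index a collection, excluding sets smaller than ``min_set_size``.

    The figure-derived collection profile uses ``min_set_size=6``; the
    default keeps everything. df and the universe are computed over the
    retained sets only. Raises :class:`EmptyCollectionError` when no set
    survives, and :class:`ValueError` on duplicate set ids.
    """
    if min_set_size < 1:
        raise ValueError("min_set_size must be >= 1")
    networks: dict[str, GeneSet] = {}
    for gs in collection:
        if len(gs.genes) < min_set_size:
            continue
        if gs.set_id in networks:
            raise ValueError(f"duplicate set id {gs.set_id!r} in collection")
        networks[gs.set_id] = gs
    if not networks:
        raise EmptyCollectionError(
            f"no gene set of size >= {min_set_size} in the collection"
        )
    inverted: dict[str, list[str]] = {}
    for set_id in sorted(networks):
        for gene in networks[set_id].genes:
            inverted.setdefault(gene, []).append(set_id)
    gene_to_sets = {g: tuple(ids) for g, ids in inverted.items()}
    return CollectionIndex(
        networks=networks,
        gene_to_sets=gene_to_sets,
        df={g: len(ids) for g, ids in gene_to_sets.items()},
        universe=frozenset(gene_to_sets),
    )


def candidate_networks(index: CollectionIndex, query: set[str]) -> list[str]:
    """Set ids of every network sharing at least one gene with the query,
    in lexicographic order. Only these can receive a score."""
    hits: set[str] = set()
    for gene in query:
        ids = index.gene_to_sets.get(gene)
        if ids:
            hits.update(ids)
    return sorted(hits)


# ---------------------------------------------------------------------------
# serialization — a portable single-file text layout:
#   line 1: "#netquery-index<TAB>v1"
#   line 2: "#m=<count><TAB>N=<universe size>"
#   then one line per network: set_id<TAB>name<TAB>source<TAB>g1 g2 g3 ...
#   (genes sorted; networks sorted by set_id)
# ---------------------------------------------------------------------------


def save_index(index: CollectionIndex, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write(f"{_HEADER}\n")
        out.write(f"#m={index.m}\tN={index.N}\n")
        for set_id in sorted(index.networks):
            gs = index.networks[set_id]
            out.write(
                "\t".join(
                    [gs.set_id, gs.name, gs.source, " ".join(sorted(gs.genes))]
                )
            )
            out.write("\n")


def load_index(path: str | os.PathLike) -> CollectionIndex:
    sets: list[GeneSet] = []
    declared_m = declared_n = None
    with open(path, "r", encoding="utf-8") as stream:
        header = stream.readline().rstrip("\n")
        if header != _HEADER:
            raise IndexFormatError(f"{path}: not a netquery v1 index file")
        counts = stream.readline().rstrip("\n")
        try:
            m_part, n_part = counts.lstrip("#").split("\t")
            declared_m = int(m_part.split("=")[1])
            declared_n = int(n_part.split("=")[1])
        except (ValueError, IndexError) as exc:
            raise IndexFormatError(f"{path}: bad count line {counts!r}") from exc
        for lineno, line in enumerate(stream, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise IndexFormatError(f"{path}:{lineno}: expected 4 columns")
            set_id, name, source, genes = parts
            sets.append(
                GeneSet(
                    set_id=set_id,
                    name=name,
                    genes=frozenset(genes.split()),
                    source=source,
                )
            )
    index = build_index(sets, min_set_size=1)
    if index.m != declared_m or index.N != declared_n:
        raise IndexFormatError(
            f"{path}: header declares m={declared_m}, N={declared_n} but "
            f"contents give m={index.m}, N={index.N}"
        )
    return index
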