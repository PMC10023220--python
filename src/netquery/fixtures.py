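"""Synthetic network collections, symbol tables and queries.

Every other module is testable offline against collections generated
here. The generator emulates the one statistical feature the scoring
model depends on: gene popularity is heavily skewed — some genes appear
in a large fraction of networks while most are rare. Gene inclusion
probability follows a Zipf-like law, P(gene of popularity rank r in a
set) ∝ r^(-s) with exponent ``gene_frequency_skew`` (default 1.0), which
exercises the IDF down-weighting that separates similarity from raw
overlap. One *planted* network whose gene set equals the query — drawn
from the rarest ranks — provides a recovery benchmark: a correct engine
must rank it first under every sort key.

All outputs are pure functions of the :class:`FixtureSpec`, including
its seed. The generator makes no attempt to mimic real pathway
topology, co-membership correlations between biologically related
genes, or curation noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cx import GeneSet, Network, Node, Edge, gene_set_to_network, write_cx, write_gmt
from .symbols import SymbolTable

__all__ = [
    "FixtureSpec",
    "generate_collection",
    "generate_symbol_table",
    "write_symbol_table",
    "generate_interactome",
    "generate_cx_corpus",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic collection.

    Defaults mirror the recovery benchmark: 500 background networks over
    a universe of 2 000 genes, with an 8-gene query of rare genes (a
    typical small experimental hit list).
    """

    n_networks: int = 500
    universe_size: int = 2000
    set_size_range: tuple[int, int] = (6, 50)
    gene_frequency_skew: float = 1.0
    planted_query_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.universe_size):
            raise ValueError(f"bad set_size_range {self.set_size_range}")
        if not (1 <= self.planted_query_size <= self.universe_size):
            raise ValueError("planted_query_size must be in [1, universe_size]")
        if self.gene_frequency_skew < 0:
            raise ValueError("gene_frequency_skew must be >= 0")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")


def _gene_names(universe_size: int) -> list[str]:
    # rank 1 (most popular) first
    return [f"G{r:05d}" for r in range(1, universe_size + 1)]


def _rank_weights(spec: FixtureSpec) -> np.ndarray:
    ranks = np.arange(1, spec.universe_size + 1, dtype=float)
    w = ranks ** (-spec.gene_frequency_skew)
    return w / w.sum()


def generate_collection(
    spec: FixtureSpec,
) -> tuple[list[GeneSet], str, set[str]]:
    """Generate background sets plus one planted network.

    Returns ``(sets, planted_set_id, query)`` where ``sets`` holds
    ``spec.n_networks`` background sets followed by the planted set,
    whose genes equal the query exactly. Background set sizes are
    uniform over ``set_size_range``; members are drawn without
    replacement with probability ∝ rank^(-skew). The query is sampled
    from the rarest decile of ranks (at least ``planted_query_size``
    of them), making it recoverable against popularity noise.
    """
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec.universe_size)
    weights = _rank_weights(spec)
    lo, hi = spec.set_size_range

    sets: list[GeneSet] = []
    width = len(str(spec.n_networks))
    for i in range(spec.n_networks):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.universe_size, size=size, replace=False, p=weights)
        sets.append(
            GeneSet(
                set_id=f"bg{i:0{width}d}",
                name=f"background network {i}",
                genes=frozenset(names[j] for j in members),
                source="synthetic",
            )
        )

    tail = max(spec.planted_query_size, spec.universe_size // 10)
    rare_ranks = np.arange(spec.universe_size - tail, spec.universe_size)
    chosen = rng.choice(rare_ranks, size=spec.planted_query_size, replace=False)
    query = {names[j] for j in chosen}
    planted = GeneSet(
        set_id="planted",
        name="planted query network",
        genes=frozenset(query),
        source="synthetic",
    )
    sets.append(planted)
    return sets, planted.set_id, query


def generate_symbol_table(
    genes: list[str] | set[str],
    alias_fraction: float = 0.3,
    previous_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], SymbolTable]:
    """An approved-symbol table over ``genes`` with synthetic aliases.

    A fraction of genes gain an alias ``<GENE>_ALT`` and/or a previous
    symbol ``<GENE>_OLD``, so normalization paths (matched, normalized,
    invalid) are all reachable. Returns the TSV rows
    ``(approved, aliases, previous)`` and the equivalent in-memory
    table.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    table = SymbolTable(approved=set())
    for g in sorted(set(genes)):
        g = g.upper()
        aliases: list[str] = []
        previous: list[str] = []
        if rng.random() < alias_fraction:
            aliases.append(f"{g}_ALT")
        if rng.random() < previous_fraction:
            previous.append(f"{g}_OLD")
        rows.append((g, "|".join(aliases), "|".join(previous)))
        table.approved.add(g)
        for a in aliases:
            table.alias_to_approved[a] = g
        for p in previous:
            table.previous_to_approved[p] = g
    return rows, table


def write_symbol_table(
    rows: list[tuple[str, str, str]], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("approved_symbol\talias_symbols\tprevious_symbols\n")
        for approved, aliases, previous in rows:
            out.write(f"{approved}\t{aliases}\t{previous}\n")


def generate_interactome(
    n_nodes: int = 200,
    n_edges: int = 600,
    seed: int = 0,
    gene_names: list[str] | None = None,
    network_id: str = "interactome",
) -> Network:
    """A random (Erdős–Rényi G(n, M)) protein-interaction-style network
    with gene-symbol node names, for subnetwork-query tests."""
    import networkx as nx

    if gene_names is None:
        gene_names = _gene_names(n_nodes)
    if len(gene_names) < n_nodes:
        raise ValueError("not enough gene names for the requested node count")
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    nodes = [Node(node_id=i, name=gene_names[i]) for i in range(n_nodes)]
    edges = [
        Edge(edge_id=j, source=u, target=v, interaction="interacts-with")
        for j, (u, v) in enumerate(sorted(g.edges()))
    ]
    return Network(
        network_id=network_id,
        name="synthetic interactome",
        nodes=nodes,
        edges=edges,
        network_attributes={"description": "synthetic random interactome"},
    )


def generate_cx_corpus(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict:
    """Materialize a full corpus on disk: every gene set as an edgeless
    CX network, the same collection as one GMT file, a random
    interactome, a symbol table, and the query.

    Returns a manifest of the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets, planted_id, query = generate_collection(spec)

    cx_dir = out / "cx"
    cx_dir.mkdir(exist_ok=True)
    for gs in sets:
        with open(cx_dir / f"{gs.set_id}.cx", "w", encoding="utf-8") as f:
            write_cx(gene_set_to_network(gs), f)

    gmt_path = out / "collection.gmt"
    with open(gmt_path, "w", encoding="utf-8") as f:
        write_gmt(sets, f)

    universe = sorted(set().union(*(gs.genes for gs in sets)))
    rows, _ = generate_symbol_table(universe, seed=spec.seed)
    table_path = out / "symbols.tsv"
    write_symbol_table(rows, table_path)

    interactome = generate_interactome(
        n_nodes=min(spec.universe_size, 500),
        n_edges=min(spec.universe_size, 500) * 3,
        seed=spec.seed,
        gene_names=_gene_names(spec.universe_size),
    )
    interactome_path = out / "interactome.cx"
    with open(interactome_path, "w", encoding="utf-8") as f:
        write_cx(interactome, f)

    query_path = out / "query.txt"
    query_path.write_text(" ".join(sorted(query)) + "\n", encoding="utf-8")

    return {
        "cx_dir": cx_dir,
        "gmt": gmt_path,
        "symbols": table_path,
        "interactome": interactome_path,
        "query": query_path,
        "planted_set_id": planted_id,
        "n_sets": len(sets),
    }
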