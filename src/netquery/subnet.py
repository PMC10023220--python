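"""On-demand queries against a single large interactome.

Unlike collection scoring, an interactome is not reduced to a gene set:
the user extracts a query-relevant subnetwork. Two query types are
supported — *direct* (induced subgraph on the matched query nodes) and
*neighborhood* (matched nodes plus everything within a fixed number of
edges, then induced). Traversal is direction-blind; recorded edge
direction survives in the output untouched. Result networks can be
annotated with a boolean ``querynode`` attribute marking the query
genes, which survives a CX round trip.
"""

from __future__ import annotations

import copy
import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .cx import Network
from .errors import EmptyGeneSetWarning
from .symbols import SymbolTable

__all__ = [
    "SubnetworkRequest",
    "direct_subnetwork",
    "neighborhood_subnetwork",
    "extract_subnetwork",
    "annotate_query_nodes",
]


@dataclass
class SubnetworkRequest:
    genes: set[str]
    mode: str = "direct"  # "direct" | "neighborhood"
    depth: int = 1
    max_nodes: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("subnetwork request needs at least one gene")
        if self.mode not in ("direct", "neighborhood"):
            raise ValueError(f"unknown query mode {self.mode!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.max_nodes is not None and self.max_nodes < 1:
            raise ValueError("max_nodes must be >= 1")


def _matched_node_ids(
    interactome: Network, genes: set[str], table: SymbolTable | None
) -> set[int]:
    """Nodes whose normalized name is one of the requested genes."""
    wanted = {g.upper() for g in genes}
    hits: set[int] = set()
    for node in interactome.nodes:
        name = node.name.strip().upper()
        if table is not None:
            resolved = table.lookup(name)
            name = resolved if resolved is not None else name
        if name in wanted:
            hits.add(node.node_id)
    return hits


def _to_graph(interactome: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in interactome.nodes)
    g.add_edges_from((e.source, e.target) for e in interactome.edges)
    return g


def _induce(interactome: Network, keep: set[int], suffix: str) -> Network:
    nodes = [copy.deepcopy(n) for n in interactome.nodes if n.node_id in keep]
    edges = [
        copy.deepcopy(e)
        for e in interactome.edges
        if e.source in keep and e.target in keep
    ]
    attrs = dict(interactome.network_attributes)
    attrs["derived_from"] = interactome.name
    attrs["description"] = (
        f"{suffix} of {interactome.name!s}"
        if interactome.description is None
        else f"{suffix} of {interactome.name!s}; source: {interactome.description}"
    )
    return Network(
        network_id=f"{interactome.network_id}__query",
        name=f"{interactome.name} ({suffix})",
        nodes=nodes,
        edges=edges,
        network_attributes=attrs,
        layout={nid: xy for nid, xy in interactome.layout.items() if nid in keep},
    )


def direct_subnetwork(
    interactome: Network,
    request: SubnetworkRequest,
    table: SymbolTable | None = None,
) -> Network:
    """Induced subgraph on the interactome nodes matching the query:
    every matched node, and every interactome edge with both endpoints
    matched. No matching node yields an empty network with a warning."""
    seeds = _matched_node_ids(interactome, request.genes, table)
    if not seeds:
        warnings.warn(
            f"no node of {interactome.network_id!r} matches the query",
            EmptyGeneSetWarning,
            stacklevel=2,
        )
    return _induce(interactome, seeds, "direct query")


def neighborhood_subnetwork(
    interactome: Network,
    request: SubnetworkRequest,
    table: SymbolTable | None = None,
) -> Network:
    """Matched nodes expanded to everything within ``depth`` edges
    (direction-blind), then induced.

    If the expansion exceeds ``max_nodes``, seeds are always kept and
    neighbors are admitted in ascending interactome-degree order (hubs
    last, so low-degree — more query-specific — neighbors survive the
    cap), then the subgraph is re-induced.
    """
    seeds = _matched_node_ids(interactome, request.genes, table)
    if not seeds:
        warnings.warn(
            f"no node of {interactome.network_id!r} matches the query",
            EmptyGeneSetWarning,
            stacklevel=2,
        )
        return _induce(interactome, set(), "neighborhood query")
    graph = _to_graph(interactome)
    dist: dict[int, int] = {s: 0 for s in seeds}
    frontier = deque(seeds)
    while frontier:
        u = frontier.popleft()
        if dist[u] == request.depth:
            continue
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)
    keep = set(dist)
    if request.max_nodes is not None and len(keep) > request.max_nodes:
        budget = max(request.max_nodes - len(seeds), 0)
        neighbors = sorted(
            (nid for nid in keep if nid not in seeds),
            key=lambda nid: (graph.degree[nid], nid),
        )
        keep = seeds | set(neighbors[:budget])
    return _induce(interactome, keep, f"neighborhood query (depth {request.depth})")


def extract_subnetwork(
    interactome: Network,
    request: SubnetworkRequest,
    table: SymbolTable | None = None,
) -> Network:
    """Dispatch on ``request.mode``."""
    if request.mode == "direct":
        return direct_subnetwork(interactome, request, table)
    return neighborhood_subnetwork(interactome, request, table)


def annotate_query_nodes(
    network: Network,
    genes: set[str],
    table: SymbolTable | None = None,
) -> Network:
    """Return a copy where every node carries boolean ``querynode``:
    true when its normalized name is a query gene, false otherwise.
    Nothing else is mutated, so saved results carry their query
    annotation through serialization."""
    hits = _matched_node_ids(network, genes, table) if genes else set()
    annotated = copy.deepcopy(network)
    for node in annotated.nodes:
        node.attributes["querynode"] = node.node_id in hits
    return annotated
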