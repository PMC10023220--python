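"""Reading and writing networks in a documented subset of the Cytoscape
Exchange (CX) format, plus reduction of networks to gene sets.

CX is a JSON-based network interchange format organized as a top-level
array of single-key "aspect" objects, each holding a list of elements::

    [
      {"metaData": [{"name": "nodes", "elementCount": 2}, ...]},
      {"networkAttributes": [{"n": "name", "v": "My pathway"}]},
      {"nodes": [{"@id": 0, "n": "TP53"}, {"@id": 1, "n": "MDM2"}]},
      {"edges": [{"@id": 0, "s": 0, "t": 1, "i": "interacts-with"}]},
      {"nodeAttributes": [{"po": 0, "n": "querynode", "v": "true",
                           "d": "boolean"}]}
    ]

This module fixes a minimal dialect sufficient for set-based network
scoring: the aspects ``nodes``, ``edges``, ``nodeAttributes``,
``edgeAttributes``, ``networkAttributes``, ``cartesianLayout`` and
``metaData`` are materialized; any other aspect is preserved opaquely so
that a read/write cycle is lossless. Attribute values are typed by a
declared ``d`` data-type field defaulting to ``string``.

The reader is incremental: the document is tokenized one aspect element
at a time on top of :meth:`json.JSONDecoder.raw_decode`, so peak parse
buffering is bounded by the largest single element, not by document
size. (The materialized :class:`Network` of course still holds every
element once parsing completes.)
"""

from __future__ import annotations

import io
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterator, TextIO

from .errors import (
    CXParseError,
    EmptyGeneSetWarning,
    ReferentialIntegrityError,
)

__all__ = [
    "Node",
    "Edge",
    "Network",
    "GeneSet",
    "read_cx",
    "write_cx",
    "to_gene_set",
    "read_gmt",
    "write_gmt",
]

#: aspects materialized into Network fields; everything else is opaque
SUPPORTED_ASPECTS = frozenset(
    {
        "nodes",
        "edges",
        "nodeAttributes",
        "edgeAttributes",
        "networkAttributes",
        "cartesianLayout",
        "metaData",
    }
)

#: reserved network attribute carrying the network identifier through a
#: round trip (CX itself has no identifier aspect in this dialect)
_ID_ATTR = "networkId"
_NAME_ATTR = "name"

AttrValue = Any  # str | bool | int | float | list of one of these


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Node:
    node_id: int
    name: str
    represents: str | None = None
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.node_id < 0:
            raise ReferentialIntegrityError(f"node id {self.node_id} < 0")
        if not self.name:
            raise ReferentialIntegrityError(
                f"node {self.node_id} has an empty name"
            )


@dataclass
class Edge:
    edge_id: int
    source: int
    target: int
    interaction: str | None = None
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edge_id < 0:
            raise ReferentialIntegrityError(f"edge id {self.edge_id} < 0")


@dataclass(eq=False)
class Network:
    """An in-memory network parsed from (or destined for) CX.

    Edge direction is recorded (``source``/``target``) but ignored by all
    set-based scoring and by subnetwork traversal. ``unknown_aspects``
    holds ``(aspect_name, elements)`` pairs preserved verbatim for
    lossless round trips. Equality is canonical: node/edge order does
    not matter.
    """

    network_id: str
    name: str = ""
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    network_attributes: dict[str, AttrValue] = field(default_factory=dict)
    layout: dict[int, tuple[float, float]] = field(default_factory=dict)
    unknown_aspects: list[tuple[str, list[Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.network_id

    # -- convenience -------------------------------------------------------

    @property
    def description(self) -> str | None:
        v = self.network_attributes.get("description")
        return None if v is None else str(v)

    @property
    def reference(self) -> str | None:
        v = self.network_attributes.get("reference")
        return None if v is None else str(v)

    def node_by_id(self) -> dict[int, Node]:
        return {n.node_id: n for n in self.nodes}

    def validate(self) -> None:
        """Raise :class:`ReferentialIntegrityError` on invariant breaches."""
        seen: set[int] = set()
        for n in self.nodes:
            if n.node_id in seen:
                raise ReferentialIntegrityError(
                    f"duplicate node id {n.node_id} in network "
                    f"{self.network_id!r}"
                )
            seen.add(n.node_id)
        eids: set[int] = set()
        for e in self.edges:
            if e.edge_id in eids:
                raise ReferentialIntegrityError(
                    f"duplicate edge id {e.edge_id} in network "
                    f"{self.network_id!r}"
                )
            eids.add(e.edge_id)
            for endpoint in (e.source, e.target):
                if endpoint not in seen:
                    raise ReferentialIntegrityError(
                        f"edge {e.edge_id} references missing node "
                        f"{endpoint} in network {self.network_id!r}"
                    )

    def _canonical(self) -> tuple:
        return (
            self.network_id,
            self.name,
            sorted(
                (n.node_id, n.name, n.represents, tuple(sorted(n.attributes.items())))
                for n in self.nodes
            ),
            sorted(
                (
                    e.edge_id,
                    e.source,
                    e.target,
                    e.interaction,
                    tuple(sorted(e.attributes.items())),
                )
                for e in self.edges
            ),
            tuple(sorted(self.network_attributes.items(), key=lambda kv: kv[0])),
            tuple(sorted(self.layout.items())),
            tuple(
                (name, json.dumps(elems, sort_keys=True))
                for name, elems in self.unknown_aspects
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._canonical() == other._canonical()


@dataclass(frozen=True)
class GeneSet:
    """A network reduced to its set of normalized, uppercase gene symbols."""

    set_id: str
    name: str
    genes: frozenset[str]
    source: str = "cx"  # one of {"cx", "gmt", "synthetic"}

    def __post_init__(self) -> None:
        for g in self.genes:
            if not g:
                raise ValueError(f"gene set {self.set_id!r} contains an empty symbol")
            if g != g.upper():
                raise ValueError(
                    f"gene set {self.set_id!r} contains non-uppercase symbol {g!r}"
                )
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# incremental tokenizer
# ---------------------------------------------------------------------------


class _StreamReader:
    """Pulls one JSON value at a time from a character stream.

    The internal buffer only ever holds the unconsumed tail of the
    stream up to the end of the value being decoded; ``max_buffer``
    records the high-water mark so tests can assert boundedness.
    """

    def __init__(self, stream: TextIO, chunk_size: int = 1 << 16) -> None:
        self._stream = stream
        self._chunk = chunk_size
        self._buf = ""
        self._eof = False
        self._decoder = json.JSONDecoder()
        self.max_buffer = 0

    def _fill(self) -> bool:
        if self._eof:
            return False
        data = self._stream.read(self._chunk)
        if not data:
            self._eof = True
            return False
        self._buf += data
        self.max_buffer = max(self.max_buffer, len(self._buf))
        return True

    def _skip_ws(self) -> None:
        while True:
            self._buf = self._buf.lstrip()
            if self._buf or not self._fill():
                return

    def next_char(self) -> str:
        """Consume and return the next non-whitespace character ('' at EOF)."""
        self._skip_ws()
        ch = self._buf[:1]
        self._buf = self._buf[1:]
        return ch

    def peek_char(self) -> str:
        self._skip_ws()
        return self._buf[:1]

    def expect(self, ch: str, context: str) -> None:
        got = self.next_char()
        if got != ch:
            raise CXParseError(
                f"{context}: expected {ch!r}, found "
                f"{(got + self._buf[:30])!r}"
            )

    def decode_value(self, context: str) -> Any:
        """Decode the next JSON value, growing the buffer only as needed."""
        self._skip_ws()
        while True:
            try:
                value, end = self._decoder.raw_decode(self._buf)
            except json.JSONDecodeError as exc:
                if self._fill():
                    continue
                raise CXParseError(f"{context}: {exc}") from exc
            # a bare number flush with the buffer end may be truncated
            if end == len(self._buf) and not self._eof and self._fill():
                continue
            self._buf = self._buf[end:]
            return value


def iter_cx_aspects(
    stream: TextIO, *, _reader_out: list | None = None
) -> Iterator[tuple[str, Any]]:
    """Yield ``(aspect_name, element)`` pairs from a CX document.

    Elements are yielded one at a time with bounded buffering. An empty
    aspect yields a single ``(aspect_name, None)`` marker so the aspect's
    presence is observable.
    """
    rd = _StreamReader(stream)
    if _reader_out is not None:
        _reader_out.append(rd)
    rd.expect("[", "CX document")
    if rd.peek_char() == "]":
        rd.next_char()
        return
    while True:
        rd.expect("{", "aspect object")
        name = rd.decode_value("aspect name")
        if not isinstance(name, str):
            raise CXParseError(f"aspect name is not a string: {name!r}")
        rd.expect(":", f"aspect {name!r}")
        rd.expect("[", f"aspect {name!r}")
        if rd.peek_char() == "]":
            rd.next_char()
            yield name, None
        else:
            while True:
                yield name, rd.decode_value(f"aspect {name!r} element")
                ch = rd.next_char()
                if ch == "]":
                    break
                if ch != ",":
                    raise CXParseError(
                        f"aspect {name!r}: expected ',' or ']', found {ch!r}"
                    )
        rd.expect("}", f"aspect {name!r}")
        ch = rd.next_char()
        if ch == "]":
            return
        if ch != ",":
            raise CXParseError(
                f"after aspect {name!r}: expected ',' or ']', found {ch!r}"
            )


# ---------------------------------------------------------------------------
# attribute value encoding
# ---------------------------------------------------------------------------

_SCALAR_DECODERS = {
    "string": str,
    "boolean": lambda v: v if isinstance(v, bool) else str(v).lower() == "true",
    "integer": int,
    "long": int,
    "double": float,
}


def _decode_attr(value: Any, datatype: str | None, context: str) -> AttrValue:
    d = datatype or "string"
    if d.startswith("list_of_"):
        inner = d[len("list_of_"):]
        if inner not in _SCALAR_DECODERS:
            raise CXParseError(f"{context}: unknown data type {d!r}")
        if not isinstance(value, list):
            raise CXParseError(f"{context}: {d} value is not a list")
        return [_SCALAR_DECODERS[inner](v) for v in value]
    if d not in _SCALAR_DECODERS:
        raise CXParseError(f"{context}: unknown data type {d!r}")
    try:
        return _SCALAR_DECODERS[d](value)
    except (TypeError, ValueError) as exc:
        raise CXParseError(f"{context}: bad {d} value {value!r}") from exc


def _scalar_datatype(value: Any) -> tuple[str, str]:
    if isinstance(value, bool):
        return ("true" if value else "false"), "boolean"
    if isinstance(value, int):
        return str(value), "integer"
    if isinstance(value, float):
        return repr(value), "double"
    if isinstance(value, str):
        return value, "string"
    raise ReferentialIntegrityError(
        f"unsupported attribute value type {type(value).__name__}"
    )


def _encode_attr(value: AttrValue) -> tuple[Any, str]:
    if isinstance(value, list):
        if not value:
            return [], "list_of_string"
        encoded, inner = zip(*(_scalar_datatype(v) for v in value))
        if len(set(inner)) != 1:
            raise ReferentialIntegrityError(
                "list attribute values must be homogeneous"
            )
        return list(encoded), f"list_of_{inner[0]}"
    return _scalar_datatype(value)


# ---------------------------------------------------------------------------
# read
# ---------------------------------------------------------------------------


def _open_source(source: str | os.PathLike | TextIO) -> TextIO:
    if isinstance(source, os.PathLike):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_cx(
    source: str | os.PathLike | TextIO,
    network_id: str | None = None,
    *,
    _reader_out: list | None = None,
) -> Network:
    """Parse a CX document into a :class:`Network`.

    ``source`` may be a text stream, a :class:`~pathlib.Path`, or a
    string holding the document itself. Raises :class:`CXParseError` on
    malformed input and :class:`ReferentialIntegrityError` when an edge
    references a node that does not exist.
    """
    stream = _open_source(source)
    close = stream is not source
    nodes: list[Node] = []
    edges: list[Edge] = []
    node_attrs: list[dict] = []
    edge_attrs: list[dict] = []
    net_attrs: dict[str, AttrValue] = {}
    layout: dict[int, tuple[float, float]] = {}
    unknown: dict[str, list[Any]] = {}
    try:
        for aspect, elem in iter_cx_aspects(stream, _reader_out=_reader_out):
            if aspect not in SUPPORTED_ASPECTS:
                unknown.setdefault(aspect, [])
                if elem is not None:
                    unknown[aspect].append(elem)
                continue
            if elem is None or aspect == "metaData":
                continue  # metaData is regenerated on write
            if not isinstance(elem, dict):
                raise CXParseError(f"aspect {aspect!r}: element is not an object")
            try:
                if aspect == "nodes":
                    nodes.append(
                        Node(
                            node_id=int(elem["@id"]),
                            name=str(elem.get("n", "")),
                            represents=(
                                str(elem["r"]) if "r" in elem and elem["r"] is not None
                                else None
                            ),
                        )
                    )
                elif aspect == "edges":
                    edges.append(
                        Edge(
                            edge_id=int(elem["@id"]),
                            source=int(elem["s"]),
                            target=int(elem["t"]),
                            interaction=(
                                str(elem["i"]) if "i" in elem and elem["i"] is not None
                                else None
                            ),
                        )
                    )
                elif aspect in ("nodeAttributes", "edgeAttributes"):
                    (node_attrs if aspect == "nodeAttributes" else edge_attrs).append(
                        {
                            "po": int(elem["po"]),
                            "n": str(elem["n"]),
                            "v": _decode_attr(
                                elem["v"], elem.get("d"), f"aspect {aspect!r}"
                            ),
                        }
                    )
                elif aspect == "networkAttributes":
                    net_attrs[str(elem["n"])] = _decode_attr(
                        elem["v"], elem.get("d"), "aspect 'networkAttributes'"
                    )
                elif aspect == "cartesianLayout":
                    layout[int(elem["node"])] = (
                        float(elem["x"]),
                        float(elem["y"]),
                    )
            except (KeyError, TypeError, ValueError) as exc:
                raise CXParseError(
                    f"aspect {aspect!r}: bad element {elem!r} ({exc})"
                ) from exc
    finally:
        if close:
            stream.close()

    by_id = {n.node_id: n for n in nodes}
    if len(by_id) != len(nodes):
        raise ReferentialIntegrityError("duplicate node identifiers in CX document")
    for rec in node_attrs:
        if rec["po"] not in by_id:
            raise ReferentialIntegrityError(
                f"nodeAttributes references missing node {rec['po']}"
            )
        by_id[rec["po"]].attributes[rec["n"]] = rec["v"]
    edge_by_id = {e.edge_id: e for e in edges}
    for rec in edge_attrs:
        if rec["po"] not in edge_by_id:
            raise ReferentialIntegrityError(
                f"edgeAttributes references missing edge {rec['po']}"
            )
        edge_by_id[rec["po"]].attributes[rec["n"]] = rec["v"]

    nid = network_id or str(net_attrs.get(_ID_ATTR, "") or "")
    name = str(net_attrs.get(_NAME_ATTR, "") or "")
    net = Network(
        network_id=nid or name or "network",
        name=name,
        nodes=nodes,
        edges=edges,
        network_attributes={
            k: v for k, v in net_attrs.items() if k not in (_ID_ATTR, _NAME_ATTR)
        },
        layout=layout,
        unknown_aspects=sorted(unknown.items()),
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------


def write_cx(network: Network, stream: TextIO | None = None) -> str | None:
    """Serialize a :class:`Network` to a CX document.

    Returns the document as a string when ``stream`` is None, otherwise
    writes to ``stream`` incrementally and returns None. Refuses (with a
    diagnostic) to serialize a network violating its invariants, so any
    emitted document parses back to an equal network.
    """
    network.validate()
    out = stream if stream is not None else io.StringIO()

    node_attr_count = sum(len(n.attributes) for n in network.nodes)
    edge_attr_count = sum(len(e.attributes) for e in network.edges)
    net_attr_elems: list[dict] = []
    for key, value in [
        (_NAME_ATTR, network.name),
        (_ID_ATTR, network.network_id),
        *sorted(network.network_attributes.items()),
    ]:
        v, d = _encode_attr(value)
        elem = {"n": key, "v": v}
        if d != "string":
            elem["d"] = d
        net_attr_elems.append(elem)

    meta = [
        {"name": "nodes", "elementCount": len(network.nodes)},
        {"name": "edges", "elementCount": len(network.edges)},
        {"name": "networkAttributes", "elementCount": len(net_attr_elems)},
    ]
    if node_attr_count:
        meta.append({"name": "nodeAttributes", "elementCount": node_attr_count})
    if edge_attr_count:
        meta.append({"name": "edgeAttributes", "elementCount": edge_attr_count})
    if network.layout:
        meta.append({"name": "cartesianLayout", "elementCount": len(network.layout)})

    out.write("[")
    _write_aspect(out, "metaData", meta, first=True)
    _write_aspect(out, "networkAttributes", net_attr_elems)

    def node_elems() -> Iterator[dict]:
        for n in sorted(network.nodes, key=lambda n: n.node_id):
            elem: dict[str, Any] = {"@id": n.node_id, "n": n.name}
            if n.represents is not None:
                elem["r"] = n.represents
            yield elem

    def edge_elems() -> Iterator[dict]:
        for e in sorted(network.edges, key=lambda e: e.edge_id):
            elem: dict[str, Any] = {"@id": e.edge_id, "s": e.source, "t": e.target}
            if e.interaction is not None:
                elem["i"] = e.interaction
            yield elem

    def attr_elems(items: list[Node] | list[Edge]) -> Iterator[dict]:
        for item in sorted(items, key=lambda x: (x.node_id if isinstance(x, Node) else x.edge_id)):
            po = item.node_id if isinstance(item, Node) else item.edge_id
            for key in sorted(item.attributes):
                v, d = _encode_attr(item.attributes[key])
                elem = {"po": po, "n": key, "v": v}
                if d != "string":
                    elem["d"] = d
                yield elem

    _write_aspect(out, "nodes", node_elems())
    _write_aspect(out, "edges", edge_elems())
    if node_attr_count:
        _write_aspect(out, "nodeAttributes", attr_elems(network.nodes))
    if edge_attr_count:
        _write_aspect(out, "edgeAttributes", attr_elems(network.edges))
    if network.layout:
        _write_aspect(
            out,
            "cartesianLayout",
            (
                {"node": nid, "x": x, "y": y}
                for nid, (x, y) in sorted(network.layout.items())
            ),
        )
    for name, elems in network.unknown_aspects:
        _write_aspect(out, name, elems)
    out.write("]")

    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


def _write_aspect(out: TextIO, name: str, elements, *, first: bool = False) -> None:
    # element-at-a-time emission keeps the writer symmetric with the reader
    if not first:
        out.write(",")
    out.write("{" + json.dumps(name) + ":[")
    sep = ""
    for elem in elements:
        out.write(sep)
        out.write(json.dumps(elem, separators=(",", ":")))
        sep = ","
    out.write("]}")


# ---------------------------------------------------------------------------
# gene set reduction and GMT
# ---------------------------------------------------------------------------


def to_gene_set(network: Network, symbol_table=None) -> GeneSet | None:
    """Reduce a network to the set of node names recognizable as genes.

    Node ``name`` fields are normalized through ``symbol_table``
    (approved > alias > previous lookup, see
    :mod:`netquery.symbols`); names absent from the table are dropped.
    Without a table, every non-empty name is kept uppercased. Returns
    None (with :class:`EmptyGeneSetWarning`) when nothing survives, so
    callers can exclude the network from indexing.
    """
    genes: set[str] = set()
    for node in network.nodes:
        token = node.name.strip().upper()
        if not token:
            continue
        if symbol_table is None:
            genes.add(token)
        else:
            approved = symbol_table.lookup(token)
            if approved is not None:
                genes.add(approved)
    if not genes:
        warnings.warn(
            f"network {network.network_id!r} has no recognizable gene symbols",
            EmptyGeneSetWarning,
            stacklevel=2,
        )
        return None
    return GeneSet(
        set_id=network.network_id,
        name=network.name,
        genes=frozenset(genes),
        source="cx",
    )


def read_gmt(source: str | os.PathLike | TextIO) -> list[GeneSet]:
    """Parse a GMT-style gene set file: ``set_id TAB name TAB gene...``.

    Genes are uppercased; blank lines are skipped; a line with no gene
    fields raises :class:`CXParseError` (the formats share an error
    channel since either can feed the indexer).
    """
    stream = _open_source(source)
    close = stream is not source
    sets: list[GeneSet] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CXParseError(
                    f"GMT line {lineno}: expected set_id, name and at least "
                    f"one gene"
                )
            set_id, name = parts[0].strip(), parts[1].strip()
            genes = frozenset(
                g.strip().upper() for g in parts[2:] if g.strip()
            )
            if not set_id or not genes:
                raise CXParseError(f"GMT line {lineno}: empty set id or gene list")
            sets.append(GeneSet(set_id=set_id, name=name or set_id, genes=genes, source="gmt"))
    finally:
        if close:
            stream.close()
    return sets


def write_gmt(sets: list[GeneSet], stream: TextIO | None = None) -> str | None:
    out = stream if stream is not None else io.StringIO()
    for gs in sets:
        out.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]))
        out.write("\n")
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


def gene_set_to_network(gene_set: GeneSet) -> Network:
    """Represent a gene set as an edgeless network (one node per gene)."""
    return Network(
        network_id=gene_set.set_id,
        name=gene_set.name,
        nodes=[Node(node_id=i, name=g) for i, g in enumerate(sorted(gene_set.genes))],
        edges=[],
    )
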