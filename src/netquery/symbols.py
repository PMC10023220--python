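"""Gene symbol normalization against an HGNC-style symbol table.

Query symbols are partitioned into three classes, mirroring how results
panels typically report them: *matched* (already an approved symbol),
*normalized* (an alias or previous symbol mapped onto its approved
symbol), and *invalid* (unrecognized). Lookup precedence is
approved > alias > previous. Ambiguous aliases — one symbol claimed by
several approved genes — are dropped at table load time, so they fall
through to *invalid* at query time.
"""

from __future__ import annotations

import csv
import io
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import TextIO

from .errors import AmbiguousSymbolWarning, EmptyQueryError, QuerySizeWarning

__all__ = [
    "SymbolTable",
    "NormalizationResult",
    "load_symbol_table",
    "normalize_query",
    "tokenize_query",
    "DEFAULT_QUERY_WARN_LIMIT",
]

#: soft query-size limit; larger queries warn but still run
DEFAULT_QUERY_WARN_LIMIT = 400

_TOKEN_SPLIT = re.compile(r"[\s,;]+")


@dataclass
class SymbolTable:
    approved: set[str] = field(default_factory=set)
    alias_to_approved: dict[str, str] = field(default_factory=dict)
    previous_to_approved: dict[str, str] = field(default_factory=dict)

    def lookup(self, symbol: str) -> str | None:
        """Resolve ``symbol`` (assumed uppercase) to an approved symbol."""
        if symbol in self.approved:
            return symbol
        hit = self.alias_to_approved.get(symbol)
        if hit is not None:
            return hit
        return self.previous_to_approved.get(symbol)

    def validate(self) -> None:
        assert not (self.approved & self.alias_to_approved.keys())
        assert not (self.approved & self.previous_to_approved.keys())
        for m in (self.alias_to_approved, self.previous_to_approved):
            for target in m.values():
                assert target in self.approved


@dataclass
class NormalizationResult:
    """The query partition: every deduplicated input token lands in
    exactly one of ``matched``, ``normalized`` (as the pair's first
    element) or ``invalid``, in input order."""

    matched: list[str]
    normalized: list[tuple[str, str]]
    invalid: list[str]
    effective_query: set[str]

    @property
    def n_tokens(self) -> int:
        return len(self.matched) + len(self.normalized) + len(self.invalid)


def load_symbol_table(source: str | os.PathLike | TextIO) -> SymbolTable:
    """Load a TSV symbol table.

    Columns: ``approved_symbol``, ``alias_symbols`` (pipe-separated),
    ``previous_symbols`` (pipe-separated); a header row with those names
    is skipped if present. All symbols are uppercased. Conflicts resolve
    as: approved status beats alias/previous status; a duplicated
    approved row is replaced by the later one; an alias claimed by two
    different approved symbols is dropped as ambiguous. Each drop emits
    an :class:`AmbiguousSymbolWarning`.
    """
    if isinstance(source, os.PathLike):
        stream: TextIO = open(source, "r", encoding="utf-8")
    elif isinstance(source, str):
        stream = io.StringIO(source)
    else:
        stream = source
    close = stream is not source

    rows: dict[str, tuple[list[str], list[str]]] = {}
    try:
        reader = csv.reader(stream, delimiter="\t")
        for row in reader:
            if not row or not row[0].strip():
                continue
            approved = row[0].strip().upper()
            if approved == "APPROVED_SYMBOL":
                continue  # header
            aliases = _split_pipe(row[1] if len(row) > 1 else "")
            previous = _split_pipe(row[2] if len(row) > 2 else "")
            if approved in rows:
                warnings.warn(
                    f"duplicate approved symbol row {approved!r}; last row wins",
                    AmbiguousSymbolWarning,
                    stacklevel=2,
                )
            rows[approved] = (aliases, previous)
    finally:
        if close:
            stream.close()

    table = SymbolTable(approved=set(rows))
    ambiguous: set[str] = set()
    for kind, index in (("alias", 0), ("previous", 1)):
        mapping = (
            table.alias_to_approved if kind == "alias" else table.previous_to_approved
        )
        for approved, cols in rows.items():
            for sym in cols[index]:
                if sym in table.approved:
                    warnings.warn(
                        f"{kind} symbol {sym!r} (of {approved!r}) is itself "
                        f"approved; approved status wins",
                        AmbiguousSymbolWarning,
                        stacklevel=2,
                    )
                    continue
                if sym in ambiguous:
                    continue
                if sym in mapping and mapping[sym] != approved:
                    warnings.warn(
                        f"{kind} symbol {sym!r} maps to both {mapping[sym]!r} "
                        f"and {approved!r}; dropped as ambiguous",
                        AmbiguousSymbolWarning,
                        stacklevel=2,
                    )
                    del mapping[sym]
                    ambiguous.add(sym)
                    continue
                mapping[sym] = approved
    return table


def _split_pipe(cell: str) -> list[str]:
    return [s.strip().upper() for s in cell.split("|") if s.strip()]


def tokenize_query(raw_query: str) -> list[str]:
    """Split on whitespace/commas/semicolons, uppercase, deduplicate
    preserving first occurrence."""
    seen: set[str] = set()
    tokens: list[str] = []
    for tok in _TOKEN_SPLIT.split(raw_query):
        tok = tok.strip().upper()
        if tok and tok not in seen:
            seen.add(tok)
            tokens.append(tok)
    return tokens


def normalize_query(
    raw_query: str,
    table: SymbolTable,
    warn_limit: int = DEFAULT_QUERY_WARN_LIMIT,
) -> NormalizationResult:
    """Partition a raw query string into matched / normalized / invalid.

    Two inputs resolving to the same approved symbol collapse to one
    effective gene (scoring is set-based) but both appear in the
    partition. Raises :class:`EmptyQueryError` when no token survives
    tokenization; queries longer than ``warn_limit`` emit a
    :class:`QuerySizeWarning` and proceed.
    """
    tokens = tokenize_query(raw_query)
    if not tokens:
        raise EmptyQueryError("query contains no gene symbols")
    if warn_limit and len(tokens) > warn_limit:
        warnings.warn(
            f"query has {len(tokens)} symbols (soft limit {warn_limit}); "
            f"large queries may be slow",
            QuerySizeWarning,
            stacklevel=2,
        )
    matched: list[str] = []
    normalized: list[tuple[str, str]] = []
    invalid: list[str] = []
    effective: set[str] = set()
    for tok in tokens:
        if tok in table.approved:
            matched.append(tok)
            effective.add(tok)
            continue
        approved = table.lookup(tok)
        if approved is not None:
            normalized.append((tok, approved))
            effective.add(approved)
        else:
            invalid.append(tok)
    return NormalizationResult(
        matched=matched,
        normalized=normalized,
        invalid=invalid,
        effective_query=effective,
    )
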