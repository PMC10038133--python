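"""Writers and readers for the two on-disk network representations.

Two text dialects and one binary format:

* ``plain`` — one ``u<TAB>v`` line per edge, ASCII decimal labels, no
  header.  Cannot represent isolated nodes, so the declared node count of a
  re-read stream is inferred as ``1 + max label``.
* ``favites`` — the FAVITES contact-network convention: one
  ``NODE<TAB>label<TAB>.`` record per node (so n round-trips), then one
  ``EDGE<TAB>u<TAB>v<TAB>.<TAB>u`` record per edge (trailing ``u`` marks the
  edge undirected); attribute fields are written empty (``.``).
* binary — one header byte holding the node width b (1, 2, 4 or 8),
  followed by both endpoints of each edge as b-byte little-endian unsigned
  integers in emission order: exactly ``2*b*|E| + 1`` bytes total.  The
  layout is this package's own dialect; only the total size is shared with
  other tools.

Writers stream: they hold a bounded buffer regardless of |E|.  Readers
materialize the edge list (plain and binary files carry no node count, so n
cannot be known before the last edge).  A path ending in ``.gz`` is
transparently gzip-compressed on both sides.
"""

from __future__ import annotations

import gzip
import io
import struct
from os import PathLike
from pathlib import Path
from typing import BinaryIO, TextIO

from .core import Edge, EdgeStream, FormatError, WidthError, max_nodes

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_binary",
    "read_binary",
]

_STRUCTS = {1: struct.Struct("<B"), 2: struct.Struct("<H"), 4: struct.Struct("<I"), 8: struct.Struct("<Q")}
_PAIR_STRUCTS = {1: struct.Struct("<2B"), 2: struct.Struct("<2H"), 4: struct.Struct("<2I"), 8: struct.Struct("<2Q")}
_FLUSH_BYTES = 1 << 16


class ParseError(FormatError):
    """A text edge-list line could not be parsed; carries the line number."""

    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def _open_text(target, mode: str):
    """Open a path for text I/O, gzip-wrapping on a .gz suffix.

    Returns (handle, should_close); file-like objects pass through.
    """
    if isinstance(target, (str, PathLike)):
        path = Path(target)
        if path.suffix == ".gz":
            return gzip.open(path, mode + "t", newline="\n"), True
        return open(path, mode, newline="\n"), True
    return target, False


def _open_binary(target, mode: str):
    if isinstance(target, (str, PathLike)):
        path = Path(target)
        if path.suffix == ".gz":
            return gzip.open(path, mode + "b"), True
        return open(path, mode + "b"), True
    return target, False


def write_edge_list(stream: EdgeStream, sink, dialect: str = "plain") -> int:
    """Write *stream* as a tab-delimited edge list; returns lines written.

    ``plain`` emits |E| ``u<TAB>v`` lines in stream order; ``favites`` emits
    n NODE records followed by |E| EDGE records.  Constant memory.
    """
    if dialect not in ("plain", "favites"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    handle, close = _open_text(sink, "w")
    lines = 0
    try:
        if dialect == "favites":
            for i in range(stream.n):
                handle.write(f"NODE\t{i}\t.\n")
                lines += 1
            for u, v in stream:
                handle.write(f"EDGE\t{u}\t{v}\t.\tu\n")
                lines += 1
        else:
            for u, v in stream:
                handle.write(f"{u}\t{v}\n")
                lines += 1
    finally:
        if close:
            handle.close()
    return lines


def read_edge_list(source, dialect: str = "plain") -> EdgeStream:
    """Read a tab-delimited edge list back into an :class:`EdgeStream`.

    Yields edges in file order.  ``plain`` infers ``n = 1 + max label``
    (0 for an empty file); ``favites`` recovers n from the NODE records.
    Malformed lines raise :class:`ParseError` with the 1-based line number.
    """
    if dialect not in ("plain", "favites"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    handle, close = _open_text(source, "r")
    edges: list[Edge] = []
    n = 0
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if dialect == "plain":
                if len(fields) != 2:
                    raise ParseError(f"expected 2 tab-separated fields, got {len(fields)}", lineno)
                try:
                    u, v = int(fields[0]), int(fields[1])
                except ValueError:
                    raise ParseError(f"non-integer node label in {line!r}", lineno) from None
                edges.append((u, v))
                n = max(n, u + 1, v + 1)
            else:
                kind = fields[0]
                if kind == "NODE":
                    if len(fields) < 2:
                        raise ParseError("NODE record missing label", lineno)
                    try:
                        n = max(n, int(fields[1]) + 1)
                    except ValueError:
                        raise ParseError(f"non-integer node label in {line!r}", lineno) from None
                elif kind == "EDGE":
                    if len(fields) < 3:
                        raise ParseError("EDGE record missing endpoints", lineno)
                    try:
                        u, v = int(fields[1]), int(fields[2])
                    except ValueError:
                        raise ParseError(f"non-integer node label in {line!r}", lineno) from None
                    edges.append((u, v))
                    n = max(n, u + 1, v + 1)
                else:
                    raise ParseError(f"unknown record type {kind!r}", lineno)
    finally:
        if close:
            handle.close()
    return EdgeStream(n, edges)


def write_binary(stream: EdgeStream, width: int, sink) -> int:
    """Write *stream* in the compact binary format; returns bytes written.

    One header byte (the width b), then 2b bytes per edge, little-endian,
    endpoints in emission orientation.  Total is exactly ``2*b*|E| + 1``.
    A label >= 2**(8b) raises :class:`WidthError` naming the offending edge.
    """
    limit = max_nodes(width)
    pair = _PAIR_STRUCTS[width]
    handle, close = _open_binary(sink, "w")
    written = 0
    try:
        buf = bytearray()
        buf.append(width)
        for u, v in stream:
            if u > limit or v > limit:
                raise WidthError(
                    f"edge ({u}, {v}) has a label exceeding the {width}-byte limit {limit}"
                )
            buf += pair.pack(u, v)
            if len(buf) >= _FLUSH_BYTES:
                handle.write(buf)
                written += len(buf)
                buf.clear()
        handle.write(buf)
        written += len(buf)
    finally:
        if close:
            handle.close()
    return written


def read_binary(source) -> EdgeStream:
    """Read the compact binary format back into an :class:`EdgeStream`.

    Recovers the exact edge sequence written, so write -> read -> write is
    byte-identical.  A header byte outside {1, 2, 4, 8} or a payload that is
    not a whole number of edge records raises :class:`FormatError`.
    """
    handle, close = _open_binary(source, "r")
    try:
        header = handle.read(1)
        if len(header) != 1:
            raise FormatError("empty file: missing width header byte")
        b = header[0]
        if b not in _STRUCTS:
            raise FormatError(f"bad width header byte {b}; expected one of 1, 2, 4, 8")
        payload = handle.read()
    finally:
        if close:
            handle.close()
    record = 2 * b
    if len(payload) % record != 0:
        raise FormatError(
            f"truncated payload: {len(payload)} bytes is not a multiple of {record}"
        )
    pair = _PAIR_STRUCTS[b]
    edges: list[Edge] = [pair.unpack_from(payload, off) for off in range(0, len(payload), record)]
    n = 0
    for u, v in edges:
        n = max(n, u + 1, v + 1)
    return EdgeStream(n, edges)
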