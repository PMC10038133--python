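"""Shared types, the streaming contract, and the seedable randomness source.

A contact network is an undirected simple graph on nodes ``0 .. n-1``.
Generators in this package never hold the whole edge set in memory: they
return an :class:`EdgeStream`, a declared node count plus a lazily produced,
single-pass sequence of edges.  Consumers (writers, pipelines) pull edges one
at a time, so peak retained state is independent of graph size for every
model except where documented otherwise.

``degree_histogram`` and ``is_connected`` are test-scale conveniences: they
must tally or union all edges and are therefore exempt from the streaming
memory contract.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Iterator

import numpy as np

__all__ = [
    "VALID_WIDTHS",
    "ParameterError",
    "WidthError",
    "FormatError",
    "Edge",
    "EdgeStream",
    "RandomSource",
    "max_nodes",
    "check_width",
    "edge_count",
    "degree_histogram",
    "is_connected",
]

#: Supported node-identifier widths, in bytes per unsigned integer label.
VALID_WIDTHS = (1, 2, 4, 8)

#: An undirected edge: an (u, v) pair of node labels with u != v.
Edge = tuple[int, int]


class ParameterError(ValueError):
    """A model parameter is outside its valid domain."""


class WidthError(ValueError):
    """A node label or node count cannot be represented at the chosen width."""


class FormatError(ValueError):
    """An on-disk representation is malformed (bad header, truncation, ...)."""


def max_nodes(b: int) -> int:
    """Largest node count representable with *b*-byte unsigned node labels.

    Parameters
    ----------
    b
        Bytes per node identifier; one of 1, 2, 4 or 8.

    Returns
    -------
    int
        ``2**(8*b) - 1``: 255, 65535, ~4.3e9 or ~1.8e19.
    """
    if b not in VALID_WIDTHS:
        raise WidthError(f"unsupported node width {b!r}; choose one of {VALID_WIDTHS}")
    return (1 << (8 * b)) - 1


def check_width(n: int, b: int) -> None:
    """Raise :class:`WidthError` if *n* nodes cannot be labelled at width *b*."""
    limit = max_nodes(b)
    if n > limit:
        raise WidthError(
            f"{n} nodes exceed the {b}-byte limit of {limit} representable nodes"
        )


class EdgeStream:
    """A declared node count plus a lazily produced finite sequence of edges.

    Single-pass: iterating consumes the stream.  All endpoints lie in
    ``[0, n)`` and no unordered edge appears twice; these invariants are
    guaranteed by the generators, not re-checked here.
    """

    __slots__ = ("n", "_edges")

    def __init__(self, n: int, edges: Iterable[Edge]):
        self.n = int(n)
        self._edges = iter(edges)

    def __iter__(self) -> Iterator[Edge]:
        return self._edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EdgeStream(n={self.n})"


class RandomSource:
    """Seedable pseudo-randomness shared by every stochastic model.

    Wraps a numpy PCG64 generator.  An identical seed and identical call
    sequence reproduce identical outputs.  Uniform doubles are drawn in
    buffered blocks for speed; this changes nothing about determinism because
    the buffer is refilled from the same underlying bit stream.
    """

    _BLOCK = 4096

    def __init__(self, seed: int | None = None):
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._buf: np.ndarray = np.empty(0)
        self._pos = 0

    def random(self) -> float:
        """Uniform real in [0, 1)."""
        if self._pos >= self._buf.shape[0]:
            self._buf = self._rng.random(self._BLOCK)
            self._pos = 0
        x = self._buf[self._pos]
        self._pos += 1
        return float(x)

    def integers(self, low: int, high: int) -> int:
        """Uniform integer in the half-open range [low, high)."""
        return int(self._rng.integers(low, high))

    def binomial(self, trials: int, p: float) -> int:
        """Exact draw from Binomial(trials, p) — never a normal approximation."""
        return int(self._rng.binomial(trials, p))


def edge_count(stream: EdgeStream | Iterable[Edge]) -> int:
    """Number of edges produced by fully consuming *stream*."""
    return sum(1 for _ in stream)


def degree_histogram(stream: EdgeStream) -> dict[int, int]:
    """Map degree -> number of nodes of that degree (test-scale utility).

    Degree-0 nodes implied by the declared node count are included, so the
    histogram's counts always sum to ``n`` and ``sum(d * c) == 2 |E|``.
    """
    deg = np.zeros(stream.n, dtype=np.int64)
    for u, v in stream:
        deg[u] += 1
        deg[v] += 1
    return dict(Counter(deg.tolist()))


def is_connected(stream: EdgeStream) -> bool:
    """True iff the graph on ``n`` nodes with the stream's edges is connected.

    Test-scale utility (union-find over all edges; materializes parent
    state of size n, exempt from the streaming contract).
    """
    n = stream.n
    if n <= 0:
        return False
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    components = n
    for u, v in stream:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            components -= 1
    return components == 1
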