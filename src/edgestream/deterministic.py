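"""Constant-memory generators for the deterministic models.

Complete, Path, Barbell, Cycle, Ring Lattice and Empty.  Each returns an
:class:`~edgestream.core.EdgeStream` whose retained state does not grow with
the node count.  Emission order is part of the contract:

* complete — lexicographic unordered pairs (u ascending, then v);
* path / cycle — chain order, cycle closes with ``(n-1, 0)`` last;
* barbell — bell A, bell B, then the bridge-and-path chain;
* ring lattice — for each node u, forward offsets ``1 .. k/2``.
"""

from __future__ import annotations

from .core import Edge, EdgeStream, ParameterError

__all__ = [
    "gen_complete",
    "gen_path",
    "gen_barbell",
    "gen_cycle",
    "gen_ring_lattice",
    "gen_empty",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def gen_complete(n: int) -> EdgeStream:
    """Complete graph: every node has an edge to every other node.

    Emits exactly ``n(n-1)/2`` edges in lexicographic order.
    """
    _require(n >= 1, f"complete graph needs n >= 1, got {n}")

    def edges():
        for u in range(n):
            for v in range(u + 1, n):
                yield (u, v)

    return EdgeStream(n, edges())


def gen_path(n: int) -> EdgeStream:
    """Path graph: n nodes connected in a linear chain; ``n-1`` edges."""
    _require(n >= 1, f"path graph needs n >= 1, got {n}")
    return EdgeStream(n, ((i, i + 1) for i in range(n - 1)))


def gen_barbell(n1: int, n2: int) -> EdgeStream:
    """Barbell graph: two complete *bells* of n1 nodes joined by an n2-node path.

    Bell A occupies nodes ``0..n1-1``, bell B ``n1..2*n1-1``, the path
    ``2*n1..2*n1+n2-1``.  The path attaches to node ``n1-1`` of bell A and
    node ``n1`` of bell B (a single direct bridge when ``n2 == 0``), so the
    graph is connected for every ``n2 >= 0``.  Total edges:
    ``n1*(n1-1) + n2 + 1``.
    """
    _require(n1 >= 2, f"barbell bells need n1 >= 2, got {n1}")
    _require(n2 >= 0, f"barbell path length must be >= 0, got {n2}")
    n = 2 * n1 + n2

    def edges():
        for bell_start in (0, n1):
            for u in range(bell_start, bell_start + n1):
                for v in range(u + 1, bell_start + n1):
                    yield (u, v)
        if n2 == 0:
            yield (n1 - 1, n1)
        else:
            first, last = 2 * n1, 2 * n1 + n2 - 1
            yield (n1 - 1, first)
            for i in range(first, last):
                yield (i, i + 1)
            yield (last, n1)

    return EdgeStream(n, edges())


def gen_cycle(n: int) -> EdgeStream:
    """Cycle graph: a path plus one edge joining its endpoints; n edges.

    Requires ``n >= 3`` — smaller cycles would need self-loops or duplicate
    edges, which no model here permits.
    """
    _require(n >= 3, f"cycle graph needs n >= 3, got {n}")

    def edges():
        for i in range(n - 1):
            yield (i, i + 1)
        yield (n - 1, 0)

    return EdgeStream(n, edges())


def gen_ring_lattice(n: int, k: int) -> EdgeStream:
    """Ring lattice: each node joined to its k nearest neighbours on a circle.

    k must be even (k/2 neighbours on each side) with ``2 <= k <= n-2``.
    Each undirected edge is emitted exactly once via forward offsets
    ``1..k/2`` mod n, giving exactly ``n*k/2`` edges and degree k everywhere.
    ``gen_ring_lattice(n, 2)`` has the same edge set as ``gen_cycle(n)``.
    """
    _require(k % 2 == 0, f"ring lattice degree k must be even, got {k}")
    _require(2 <= k <= n - 2, f"ring lattice needs 2 <= k <= n-2, got n={n}, k={k}")

    def edges():
        half = k // 2
        for u in range(n):
            for d in range(1, half + 1):
                yield (u, (u + d) % n)

    return EdgeStream(n, edges())


def gen_empty(n: int) -> EdgeStream:
    """Edgeless graph on n declared nodes."""
    _require(n >= 1, f"empty graph needs n >= 1, got {n}")
    return EdgeStream(n, iter(()))
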