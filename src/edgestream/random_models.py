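"""Stochastic contact-network models sampled as lazy edge streams.

Erdős–Rényi G(n, p) comes in two distributionally identical flavours: a
naive per-pair Bernoulli sweep (O(n^2) time) and a geometric skip-sampler
(expected O(n + |E|) time), both O(1) retained state.  Barabási–Albert
preferential attachment keeps an O(nm) working set of repeated endpoints.
The Newman–Watts–Strogatz small-world sampler needs only the shortcut edges
in memory: it streams the ring lattice, draws the number of shortcuts as a
single Binomial(nk/2, p) variate, and samples shortcut *cells* uniformly
without replacement from a flat integer range that is in exact bijection
with the admissible non-lattice node pairs.

The shortcut-cell bijection
---------------------------

After the ring lattice on n nodes with even degree k, each node u has
``n - k - 1`` admissible new partners, laid out as a conceptual n-row matrix
whose cell (u, j) holds partner ``w = (u + k/2 + 1 + j) mod n``.  Keeping
one orientation of each unordered pair leaves ``n (n - k - 1) / 2``
admissible cells: rows ``0 .. k/2`` are full (length ``n - k - 1``), and
rows ``k/2 + 1 .. n - k/2 - 2`` form a triangular tail of lengths
``n - k - 2, n - k - 3, ..., 1``.  Flattening these cells row-major gives a
bijection between ``[0, n(n-k-1)/2)`` and the non-lattice pairs; its inverse
uses exact integer triangular-number inversion (isqrt with a post-check), so
it is exact even at 8-byte node widths.
"""

from __future__ import annotations

import math
import warnings

from .core import Edge, EdgeStream, ParameterError, RandomSource
from .deterministic import gen_complete, gen_ring_lattice

__all__ = [
    "gen_er_naive",
    "gen_er_fast",
    "gen_ba",
    "gen_nws",
    "gen_nws_naive",
    "nws_admissible_count",
    "nws_cell_to_index",
    "nws_index_to_edge",
    "sample_distinct_integers",
]


def _check_er(n: int, p: float) -> None:
    if n < 1:
        raise ParameterError(f"G(n,p) needs n >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"edge probability must lie in [0, 1], got {p}")


def gen_er_naive(n: int, p: float, rng: RandomSource) -> EdgeStream:
    """G(n, p) by one Bernoulli(p) trial per unordered pair.

    Iterates all C(n, 2) pairs in lexicographic order with O(1) retained
    state; O(n^2) time, so suited to small n or dense p.
    """
    _check_er(n, p)

    def edges():
        for u in range(n):
            for v in range(u + 1, n):
                if rng.random() < p:
                    yield (u, v)

    return EdgeStream(n, edges())


def _pair_from_rank(x: int, n: int) -> Edge:
    """The x-th unordered pair (0-based) in lexicographic order over n nodes.

    Row u starts at rank ``u*(n-1) - u*(u-1)/2``; u is recovered by exact
    integer quadratic inversion (isqrt plus a +/-1 post-check).
    """
    # Solve u*(2n - 1 - u)/2 <= x for the largest integer u.
    a = 2 * n - 1
    u = (a - math.isqrt(a * a - 8 * x)) // 2

    def row_start(r: int) -> int:
        return r * (2 * n - 1 - r) // 2

    while row_start(u + 1) <= x:
        u += 1
    while row_start(u) > x:
        u -= 1
    v = u + 1 + (x - row_start(u))
    return (u, v)


def gen_er_fast(n: int, p: float, rng: RandomSource) -> EdgeStream:
    """G(n, p) by geometric skip-sampling over the lexicographic pair sequence.

    Between consecutive included pairs the gap is geometric: draw
    r ~ Uniform(0,1) and advance ``1 + floor(log(1-r) / log(1-p))``
    positions.  Expected time O(n + |E|), O(1) retained state, and the
    sampled graph distribution is identical to :func:`gen_er_naive`.
    p = 0 and p = 1 are special-cased (the skip divides by log(1-p)).
    """
    _check_er(n, p)
    if p == 0.0:
        return EdgeStream(n, iter(()))
    if p == 1.0:
        return gen_complete(n)

    total = n * (n - 1) // 2
    log_q = math.log1p(-p)

    def edges():
        pos = -1
        while True:
            r = rng.random()
            pos += 1 + int(math.log1p(-r) / log_q)
            if pos >= total:
                return
            yield _pair_from_rank(pos, n)

    return EdgeStream(n, edges())


def gen_ba(n: int, m: int, rng: RandomSource) -> EdgeStream:
    """Barabási–Albert preferential attachment with exactly m(n-m) edges.

    Nodes ``0..m-1`` form the initial target set.  Each new node
    ``v = m..n-1`` connects to m distinct existing targets drawn uniformly
    from the list of repeated edge endpoints (redrawing on duplicates), which
    realises linear preferential attachment; v and its targets are then
    appended to that list.  Working memory is the O(nm) endpoint list; the
    graph is simple and connected.
    """
    if m < 1 or m >= n:
        raise ParameterError(f"preferential attachment needs 1 <= m < n, got n={n}, m={m}")

    def edges():
        repeat: list[int] = []
        targets = list(range(m))
        for v in range(m, n):
            for t in targets:
                yield (t, v)
            repeat.extend(targets)
            repeat.extend([v] * m)
            if v + 1 < n:
                chosen: set[int] = set()
                while len(chosen) < m:
                    chosen.add(repeat[rng.integers(0, len(repeat))])
                targets = sorted(chosen)

    return EdgeStream(n, edges())


def _check_nws(n: int, k: int) -> None:
    if k % 2 != 0:
        raise ParameterError(f"small-world lattice degree k must be even, got {k}")
    if not 2 <= k <= n - 2:
        raise ParameterError(f"small-world model needs 2 <= k <= n-2, got n={n}, k={k}")


def nws_admissible_count(n: int, k: int) -> int:
    """Number of admissible shortcut cells, ``n (n - k - 1) / 2``.

    Equals C(n, 2) minus the nk/2 lattice edges; the product is always even
    for even k, so integer division is exact.
    """
    _check_nws(n, k)
    return n * (n - k - 1) // 2


def nws_cell_to_index(row: int, col: int, n: int, k: int) -> int:
    """Flattened array index of admissible matrix cell (row, col).

    Rows ``0..k/2`` are full with ``n-k-1`` cells; row ``k/2 + 1 + t`` of the
    triangular tail keeps its first ``n-k-2-t`` cells.  Inverse of
    :func:`nws_index_to_edge`'s cell-recovery step.
    """
    _check_nws(n, k)
    ncols = n - k - 1
    half = k // 2
    if not 0 <= row <= n - half - 2:
        raise ParameterError(f"row {row} holds no admissible cells for n={n}, k={k}")
    if row <= half:
        row_len = ncols
        start = row * ncols
    else:
        t = row - half - 1
        row_len = ncols - 1 - t
        start = (half + 1) * ncols + t * (ncols - 1) - t * (t - 1) // 2
    if not 0 <= col < row_len:
        raise ParameterError(
            f"column {col} is disregarded in row {row} for n={n}, k={k}"
        )
    return start + col


def nws_index_to_edge(x: int, n: int, k: int) -> Edge:
    """Map flattened shortcut index x to its unordered non-lattice edge.

    Inverts the row-major flattening: inside the full rows this is a
    division; inside the triangular tail the row is found by exact integer
    triangular-number inversion (isqrt with post-check, no floating point).
    The partner is then ``w = (row + k/2 + 1 + col) mod n``.
    """
    _check_nws(n, k)
    total = n * (n - k - 1) // 2
    if not 0 <= x < total:
        raise IndexError(f"shortcut index {x} outside [0, {total}) for n={n}, k={k}")
    ncols = n - k - 1
    half = k // 2
    full = (half + 1) * ncols
    if x < full:
        row, col = divmod(x, ncols)
    else:
        y = x - full
        m = ncols - 1  # first tail row length
        # largest t with t*m - t*(t-1)/2 <= y
        a = 2 * m + 1
        t = (a - math.isqrt(a * a - 8 * y)) // 2

        def tail_start(s: int) -> int:
            return s * m - s * (s - 1) // 2

        while tail_start(t + 1) <= y:
            t += 1
        while tail_start(t) > y:
            t -= 1
        row = half + 1 + t
        col = y - tail_start(t)
    w = (row + half + 1 + col) % n
    return (row, w)


def sample_distinct_integers(s: int, upper: int, rng: RandomSource) -> set[int]:
    """s distinct uniform integers from [0, upper], in O(s) memory.

    Floyd's subset-sampling algorithm: every s-subset of the range is equally
    likely, each element costs one uniform draw, and no state proportional to
    the range size is kept.
    """
    if s < 0 or s > upper + 1:
        raise ParameterError(f"cannot draw {s} distinct integers from [0, {upper}]")
    chosen: set[int] = set()
    for j in range(upper + 1 - s, upper + 1):
        t = rng.integers(0, j + 1)
        chosen.add(j if t in chosen else t)
    return chosen


def gen_nws(n: int, k: int, p: float, rng: RandomSource) -> EdgeStream:
    """Newman–Watts–Strogatz small-world graph, keeping only shortcuts in memory.

    Streams the nk/2 ring-lattice edges, then draws the shortcut count
    ``S ~ Binomial(nk/2, p)`` in one variate (one Bernoulli(p) trial per
    lattice edge), samples S distinct cell indices uniformly without
    replacement, and maps each through :func:`nws_index_to_edge`.  Shortcuts
    can never duplicate lattice edges because the bijection's range excludes
    them.  Retained memory O(S); the graph always contains the connected
    ring lattice, hence is always connected.

    When k > (n-1)/2 the binomial draw can exceed the admissible cell count;
    S is then clamped to it with a warning.
    """
    _check_nws(n, k)
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"shortcut probability must lie in [0, 1], got {p}")
    admissible = n * (n - k - 1) // 2
    s = rng.binomial(n * k // 2, p)
    if s > admissible:
        warnings.warn(
            f"shortcut draw {s} exceeds the {admissible} admissible cells "
            f"for n={n}, k={k}; clamping",
            stacklevel=2,
        )
        s = admissible
    shortcut_cells = sorted(sample_distinct_integers(s, admissible - 1, rng))

    def edges():
        yield from gen_ring_lattice(n, k)
        for x in shortcut_cells:
            yield nws_index_to_edge(x, n, k)

    return EdgeStream(n, edges())


def gen_nws_naive(n: int, k: int, p: float, rng: RandomSource) -> EdgeStream:
    """Reference small-world sampler holding full adjacency in memory.

    For each lattice edge (u, v), with probability p a shortcut (u, w) is
    added, w drawn uniformly from the nodes not already adjacent to u (and
    not u itself).  Test-scale only: the distributional oracle for
    :func:`gen_nws` on aggregate statistics (edge and shortcut counts).
    """
    _check_nws(n, k)
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"shortcut probability must lie in [0, 1], got {p}")

    adj: list[set[int]] = [set() for _ in range(n)]
    lattice: list[Edge] = []
    for u, v in gen_ring_lattice(n, k):
        adj[u].add(v)
        adj[v].add(u)
        lattice.append((u, v))
    shortcuts: list[Edge] = []
    for u, _v in lattice:
        if rng.random() < p:
            candidates = [w for w in range(n) if w != u and w not in adj[u]]
            if not candidates:
                continue  # u saturated; no admissible partner remains
            w = candidates[rng.integers(0, len(candidates))]
            adj[u].add(w)
            adj[w].add(u)
            shortcuts.append((u, w))

    def edges():
        yield from lattice
        yield from shortcuts

    return EdgeStream(n, edges())
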