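# Methods

## Scope and model definitions

`edgestream` samples undirected simple graphs on nodes `0 .. n-1` from nine
models and emits them as single-pass lazy edge streams. Nodes are
consecutive 0-based integers; no model produces self-loops or duplicate
unordered edges. Emission order is part of each generator's contract (it
fixes the byte-level output): lexicographic pairs for the complete graph and
both G(n, p) samplers; chain order for path and cycle (the cycle closes with
`(n-1, 0)`); bell A, bell B, then the bridge-and-path chain for the barbell;
per-node forward offsets `1..k/2` for the ring lattice; per-new-node target
edges for preferential attachment; lattice edges then sorted shortcut cells
for the small-world model.

The barbell attaches its path to node `n1-1` of the first bell and node `n1`
of the second (a single direct bridge when `n2 = 0`), the usual construction,
which keeps the graph connected for every `n2 ≥ 0`. Cycles require `n ≥ 3`:
smaller cycles would demand self-loops or parallel edges, so they are
rejected rather than bent into shape. Ring lattices require even `k` with
`2 ≤ k ≤ n-2`; `k = n-1`-style dense lattices are rejected because mod-n
forward offsets would emit duplicate edges.

## Randomness

All stochastic models draw from a single `RandomSource`, a thin wrapper over
numpy's PCG64 (`np.random.default_rng`). One seed fixes the whole run:
identical seed and call sequence reproduce identical streams, and the CLI
logs an entropy-drawn seed when none is given. Uniform doubles are drawn in
blocks of 4096 for speed; the block is refilled from the same bit stream, so
buffering does not affect determinism. Binomial variates use numpy's exact
binomial sampler — never a normal approximation, which matters for the small
`nk/2` trial counts exercised in the tests.

## Erdős–Rényi sampling

The naive sampler performs one Bernoulli(p) trial per unordered pair in
lexicographic order: O(n²) time, O(1) state. The fast sampler skip-samples
the same pair sequence: with inclusion probability p, the gap between
included pairs is geometric, so it advances `1 + ⌊log1p(−r)/log1p(−p)⌋`
positions per uniform draw r and lands exactly on the included pairs —
expected O(n + |E|) time, O(1) state, identical graph distribution. The
linear pair rank is converted to a pair by exact integer quadratic inversion
(`isqrt` plus a ±1 post-check), so ranks are exact at any width; only the
logarithm uses floating point, which affects gap lengths' distribution not
at all (it is the standard inverse-CDF geometric draw). p = 0 and p = 1 are
special-cased because the skip formula divides by log(1−p).

## Barabási–Albert sampling

Nodes `0..m-1` seed the target set; each new node v connects to m distinct
targets and then v (m times) and its targets are appended to a repeated-
endpoints list, from which the next node's targets are drawn uniformly with
rejection of duplicates — linear preferential attachment. The first new node
deterministically attaches to all of `0..m-1`, which makes the graph
connected and gives exactly m(n−m) edges. Working memory is the O(nm)
endpoint list; this is the one model (besides the small-world shortcut set)
exempt from the O(1)-state guarantee. Targets are emitted in sorted order,
a fixed tie-break that makes seeded runs byte-stable.

## The small-world shortcut bijection

After the ring lattice on n nodes with even degree k, node u's admissible
new partners are the `n-k-1` nodes `(u + k/2 + 1 + j) mod n`,
`j = 0..n-k-2`. Discarding the mirror orientation of each unordered pair
leaves `n(n-k-1)/2` admissible cells: rows `0..k/2` are full (all `n-k-1`
columns), and rows `k/2+1 .. n-k/2-2` form a triangular tail of lengths
`n-k-2, n-k-3, ..., 1`. Flattening row-major assigns each cell a unique
index; the inverse map divides within the full block and inverts a
triangular number within the tail, using `math.isqrt` with a ±1 post-check
so the arithmetic is exact even for 8-byte node labels (floating-point sqrt
would misplace cells beyond 2⁵³).

Sampling is then: draw `S ~ Binomial(nk/2, p)` (one trial per lattice edge,
collapsed into a single variate), sample S distinct indices uniformly from
the admissible range, map each to its pair. Only the S shortcut cells are
retained; lattice edges are streamed. Because the index range is exactly the
complement of the lattice, shortcuts can never duplicate lattice edges, and
since the lattice is connected the sampled graph always is.

Corner case: when `k > (n-1)/2` there are more lattice edges than admissible
cells, so the binomial draw can exceed the range. S is clamped to the
admissible count with a `UserWarning`; the alternative (erroring) would make
otherwise-valid dense parameterisations unusable.

Distinct indices come from Floyd's subset-sampling algorithm: one uniform
integer draw per element, O(S) memory, and every S-subset equally likely at
any S-to-range ratio, with no fallback path to reason about. Shortcut cells
are emitted in sorted index order — a fixed, documented order that costs
O(S log S) and keeps seeded output byte-stable.

A reference sampler (`gen_nws_naive`) holds full adjacency and, per lattice
edge (u, v), adds a shortcut (u, w) with probability p, w uniform over the
non-neighbours of u. The literature leaves w's distribution underspecified;
the cell-uniform distribution of the efficient sampler is treated as
normative, and the two are compared on the aggregate statistics they
provably share (shortcut-count and edge-count distributions) by a two-sample
chi-square test. If a trial succeeds when u is already adjacent to everyone,
the naive sampler skips it — the analogue of the efficient sampler's clamp.

## File formats

* **plain** — `u<TAB>v` per edge, ASCII decimal, newline-terminated. Cannot
  represent isolated nodes; a re-read stream's node count is inferred as
  `1 + max label`. Use the FAVITES dialect when n must survive a round-trip
  (edgeless or very sparse graphs).
* **favites** — `NODE<TAB>label<TAB>.` per node, then
  `EDGE<TAB>u<TAB>v<TAB>.<TAB>u` per edge; attribute fields are written
  empty (`.`), and the trailing `u` marks edges undirected.
* **binary** — one header byte holding the width b ∈ {1, 2, 4, 8}, then both
  endpoints of each edge as b-byte little-endian unsigned integers in
  emission orientation: exactly `2·b·|E| + 1` bytes. Only the total size is
  a published property of the format this mirrors; header semantics,
  endianness and edge order are this package's own dialect and are not
  claimed byte-compatible with other tools.

Writers stream through a 64 KiB buffer regardless of |E|. Readers
materialize edges, since plain and binary files carry no node count. A
`.gz` path suffix selects transparent gzip on both sides.

`degree_histogram` and `is_connected` (union-find) are test-scale
conveniences that tally or union every edge; they are documented as exempt
from the streaming memory contract.

## Validation approach and problem sizes

The test suite verifies, at sizes chosen to keep the full run around ten
seconds:

* closed-form edge counts for every model, including 100 random
  Barabási–Albert parameter draws at exactly m(n−m);
* the shortcut bijection exhaustively against brute-force enumeration for
  all valid (n, k) with n ≤ 25, plus exactness spot-checks at n = 10⁹;
* distributional equivalence of the two G(n, p) samplers at n = 30,
  p ∈ {0.05, 0.2}, 5000 replicates each: fixed-pair inclusion frequency
  within the 99% binomial CI and a chi-square goodness-of-fit of total edge
  counts against Binomial(435, p) at α = 0.01;
* small-world guarantees: 200 random parameterisations (n ≤ 60) all
  connected; shortcut counts at n = 9, k = 2, p = 0.3 over 4000 replicates
  fitting Binomial(9, 0.3); naive-vs-efficient shortcut-count agreement at
  n = 8, k = 2, p = 0.6, 5000 replicates per sampler;
* the binary size law and byte-identical round-trips over a models × widths
  matrix, and streaming laziness via bounded-prefix timing on 10⁸-node
  graphs.

Statistical tests use fixed seeds, so they are deterministic in practice;
the α = 0.01 thresholds mean a re-seeded run would fail each such test with
probability about 1%.

## Limitations

Synthetic networks from these models emulate the *structure* of contact
networks (density, scale-free degree tails, small-world clustering), not
their demography: no household/school/workplace layering, no degree
assortativity, no temporal contacts. Passing tests show the samplers match
their mathematical definitions, not that any model matches a real
population. Directed graphs, node/edge attributes, rewiring-based
Watts–Strogatz variants, and degree-sequence or stochastic-block models are
out of scope, as is any graph analysis beyond the two test-scale utilities.
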