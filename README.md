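# edgestream

Memory-efficient streaming generation of contact networks for epidemic
simulation.

Epidemic simulation pipelines (e.g. those built around FAVITES) start from a
*contact network*: an undirected graph whose nodes are individuals and whose
edges are contacts capable of transmitting a pathogen. Generating such
networks with general-purpose graph libraries requires holding the whole
graph in memory, which becomes prohibitive at global scale. `edgestream`
instead samples each network model as a **lazy edge stream**: edges are
produced one at a time and written straight to disk or to a pipe, so peak
memory is independent of graph size for every model except where the model
itself requires working state.

## Models

| model | parameters | edges |
|---|---|---|
| complete | n | n(n−1)/2 |
| path | n | n−1 |
| cycle | n | n |
| empty | n | 0 |
| barbell | n1, n2 | n1(n1−1) + n2 + 1 |
| ringlattice | n, k (even) | nk/2 |
| Erdős–Rényi G(n, p) | n, p | Binomial(C(n,2), p) |
| Barabási–Albert | n, m | exactly m(n−m) |
| Newman–Watts–Strogatz | n, k, p | nk/2 + Binomial(nk/2, p) |

Two algorithmic ideas carry the memory guarantee for the stochastic models:

* **G(n, p) by geometric skipping** — instead of one Bernoulli(p) trial per
  pair, the sampler jumps between included pairs with geometrically
  distributed gaps (`1 + ⌊log(1−r)/log(1−p)⌋` positions per jump), giving
  expected O(n + |E|) time and O(1) state, with the same graph distribution
  as the naive per-pair sweep.
* **Small-world shortcuts by an exact index bijection** — the
  Newman–Watts–Strogatz model adds a shortcut per ring-lattice edge with
  probability p. The shortcut count is drawn once as S ~ Binomial(nk/2, p);
  S distinct integers are then sampled from [0, n(n−k−1)/2) and mapped
  through an exact integer bijection onto the node pairs *not* in the
  lattice. Only the S shortcuts are ever held in memory, and a shortcut can
  never collide with a lattice edge. The resulting graph always contains the
  connected ring lattice, so it is always connected.

Node identifiers are unsigned integers of a selectable width b ∈ {1, 2, 4, 8}
bytes (up to 255, 65,535, ~4.3 billion, or ~1.8×10¹⁹ nodes). Output formats:
plain tab-delimited edge list, the FAVITES NODE/EDGE record dialect, and a
compact binary format of exactly 2·b·|E| + 1 bytes; any output path ending in
`.gz` is gzip-compressed transparently.

## Worked example

Sample a small-world contact network on 10 nodes (lattice degree 4, shortcut
probability 0.1) with a fixed seed:

```sh
$ edgestream nws -n 10 -k 4 -p 0.1 --seed 42
0	1
0	2
1	2
...
9	1
2	5
3	6
6	9
edgestream: model=nws n=10 edges=23 seed=42 format=tsv width=4
```

The first 20 lines are the ring-lattice edges (each node joined to its two
nearest neighbours on each side); the last three — (2,5), (3,6), (6,9) — are
the sampled shortcuts, so |E| = nk/2 + S = 20 + 3. The same graph is
available in-process:

```python
>>> from edgestream import RandomSource, gen_nws
>>> edges = list(gen_nws(10, 4, 0.1, RandomSource(42)))
>>> len(edges)
23
```

Identical seeds give byte-identical output; without `--seed`, a seed is drawn
from system entropy and logged to standard error so the run can be replayed.

The shortcut bijection itself is exposed directly: for n = 7, k = 2 there are
n(n−k−1)/2 = 14 admissible shortcut cells, and

```python
>>> from edgestream import nws_index_to_edge
>>> nws_index_to_edge(13, 7, 2)
(4, 6)
```

maps the final flat index to the last admissible pair.

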