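"""Stochastic generators: exact counts, marginals, distributional oracles."""

import math

import numpy as np
import pytest
from conftest import two_sample_count_pvalue, unordered

from edgestream import (
    ParameterError,
    RandomSource,
    edge_count,
    gen_ba,
    gen_er_fast,
    gen_er_naive,
    gen_nws,
    gen_nws_naive,
    gen_ring_lattice,
    is_connected,
    sample_distinct_integers,
)


class TestErdosRenyi:
    @pytest.mark.parametrize("sampler", [gen_er_naive, gen_er_fast])
    def test_degenerate_probabilities(self, sampler):
        assert edge_count(sampler(25, 0.0, RandomSource(0))) == 0
        assert unordered(sampler(5, 1.0, RandomSource(0))) == unordered(
            [(u, v) for u in range(5) for v in range(u + 1, 5)]
        )

    @pytest.mark.parametrize("sampler", [gen_er_naive, gen_er_fast])
    def test_simple_graph_with_valid_endpoints(self, sampler):
        n = 50
        edges = list(sampler(n, 0.15, RandomSource(7)))
        pairs = unordered(edges)
        assert all(0 <= u < n and 0 <= v < n for u, v in pairs)

    @pytest.mark.parametrize("sampler", [gen_er_naive, gen_er_fast])
    def test_reproducible_under_seed(self, sampler):
        a = list(sampler(60, 0.1, RandomSource(99)))
        b = list(sampler(60, 0.1, RandomSource(99)))
        assert a == b

    def test_naive_mean_edge_count_matches_expectation(self):
        """Mean of 2000 G(40, 0.1) edge counts sits in the 99% CI of 0.1*C(40,2)."""
        n, p, reps = 40, 0.1, 2000
        rng = RandomSource(2024)
        pairs = n * (n - 1) // 2
        counts = [edge_count(gen_er_naive(n, p, rng)) for _ in range(reps)]
        expect = p * pairs  # 78.0
        half_width = 2.576 * math.sqrt(pairs * p * (1 - p) / reps)
        assert abs(np.mean(counts) - expect) < half_width

    def test_fast_per_pair_marginal_equals_p(self):
        """Skip-sampling must include any fixed pair with probability exactly p."""
        n, p, reps = 30, 0.2, 5000
        rng = RandomSource(31)
        hits = sum((0, 1) in set(gen_er_fast(n, p, rng)) for _ in range(reps))
        half_width = 2.576 * math.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < half_width

    def test_invalid_probability_rejected(self):
        for bad in (-0.1, 1.5):
            with pytest.raises(ParameterError):
                gen_er_naive(10, bad, RandomSource(0))
            with pytest.raises(ParameterError):
                gen_er_fast(10, bad, RandomSource(0))


class TestBarabasiAlbert:
    @pytest.mark.parametrize("n, m", [(10, 3), (50, 1), (6, 5), (40, 7), (2, 1)])
    def test_exact_edge_count_and_simplicity(self, n, m):
        edges = list(gen_ba(n, m, RandomSource(5)))
        assert len(edges) == m * (n - m)
        pairs = unordered(edges)
        assert all(0 <= u < n and 0 <= v < n for u, v in pairs)

    def test_m1_gives_connected_tree(self):
        edges = list(gen_ba(5, 1, RandomSource(11)))
        assert len(edges) == 4
        assert is_connected(_restream(5, edges))

    def test_single_iteration_selects_all_initial_targets(self):
        # n = m+1: node m must attach to every node 0..m-1
        m = 4
        edges = unordered(gen_ba(m + 1, m, RandomSource(3)))
        assert edges == {frozenset((t, m)) for t in range(m)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_connected(self, seed):
        edges = list(gen_ba(40, 3, RandomSource(seed)))
        assert is_connected(_restream(40, edges))

    def test_reproducible_under_seed(self):
        assert list(gen_ba(30, 2, RandomSource(8))) == list(gen_ba(30, 2, RandomSource(8)))

    @pytest.mark.parametrize("n, m", [(5, 0), (5, 5), (3, 7)])
    def test_invalid_parameters_rejected(self, n, m):
        with pytest.raises(ParameterError):
            gen_ba(n, m, RandomSource(0))


class TestSampleDistinctIntegers:
    def test_degenerate_sizes(self):
        rng = RandomSource(0)
        assert sample_distinct_integers(0, 9, rng) == set()
        assert sample_distinct_integers(10, 9, rng) == set(range(10))

    def test_requested_size_and_range(self):
        rng = RandomSource(4)
        got = sample_distinct_integers(5, 99, rng)
        assert len(got) == 5
        assert all(0 <= x <= 99 for x in got)

    def test_oversized_request_rejected(self):
        with pytest.raises(ParameterError):
            sample_distinct_integers(11, 9, RandomSource(0))

    def test_uniform_inclusion_frequency(self):
        """Each of 10 integers appears in a 2-subset with frequency 0.2 (99% CI)."""
        reps = 20000
        rng = RandomSource(77)
        hits = np.zeros(10)
        for _ in range(reps):
            for x in sample_distinct_integers(2, 9, rng):
                hits[x] += 1
        half_width = 2.576 * math.sqrt(0.2 * 0.8 / reps)
        assert np.all(np.abs(hits / reps - 0.2) < half_width)


class TestNewmanWattsStrogatz:
    def test_p0_is_exactly_the_ring_lattice(self):
        assert unordered(gen_nws(12, 4, 0.0, RandomSource(0))) == unordered(
            gen_ring_lattice(12, 4)
        )
        assert unordered(gen_nws_naive(12, 4, 0.0, RandomSource(0))) == unordered(
            gen_ring_lattice(12, 4)
        )

    def test_p1_small_case_edge_count(self):
        # Binomial(7, 1) = 7 shortcuts on top of the 7 lattice edges
        assert edge_count(gen_nws(7, 2, 1.0, RandomSource(1))) == 14

    def test_shortcuts_never_duplicate_lattice_edges(self):
        lattice = unordered(gen_ring_lattice(20, 4))
        for seed in range(5):
            edges = list(gen_nws(20, 4, 0.8, RandomSource(seed)))
            pairs = unordered(edges)  # would fail on any duplicate
            assert len(pairs) == len(edges)
            assert lattice <= pairs

    def test_overflow_shortcut_draw_is_clamped(self):
        # n=6, k=4: 12 lattice edges but only n(n-k-1)/2 = 3 admissible cells
        with pytest.warns(UserWarning, match="clamp"):
            edges = list(gen_nws(6, 4, 1.0, RandomSource(0)))
        assert len(edges) == 12 + 3

    def test_naive_mean_edge_count(self):
        """Naive sampler: E|edges| = nk/2 + (nk/2) p; 4000-rep mean in the 99% CI."""
        n, k, p, reps = 9, 2, 0.5, 4000
        rng = RandomSource(55)
        counts = [edge_count(gen_nws_naive(n, k, p, rng)) for _ in range(reps)]
        expect = 9 + 4.5
        half_width = 2.576 * math.sqrt(9 * p * (1 - p) / reps)
        assert abs(np.mean(counts) - expect) < half_width

    def test_naive_and_efficient_shortcut_counts_agree(self):
        """Two-sample chi-square on shortcut-count tables does not reject at 1%."""
        n, k, p, reps = 8, 2, 0.6, 5000
        lattice_edges = n * k // 2
        rng_a, rng_b = RandomSource(101), RandomSource(202)
        a = [edge_count(gen_nws_naive(n, k, p, rng_a)) - lattice_edges for _ in range(reps)]
        b = [edge_count(gen_nws(n, k, p, rng_b)) - lattice_edges for _ in range(reps)]
        assert two_sample_count_pvalue(a, b) > 0.01

    def test_reproducible_under_seed(self):
        assert list(gen_nws(30, 4, 0.3, RandomSource(9))) == list(
            gen_nws(30, 4, 0.3, RandomSource(9))
        )

    @pytest.mark.parametrize("n, k, p", [(10, 3, 0.1), (5, 4, 0.1), (10, 2, 1.4)])
    def test_invalid_parameters_rejected(self, n, k, p):
        with pytest.raises(ParameterError):
            gen_nws(n, k, p, RandomSource(0))


def _restream(n, edges):
    from edgestream import EdgeStream

    return EdgeStream(n, edges)
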