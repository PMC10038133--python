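"""Shared helpers for the test suite."""

from collections import Counter

import numpy as np
from scipy import stats


def unordered(edges):
    """Edge sequence -> set of unordered pairs; also asserts no duplicates."""
    seen = set()
    for u, v in edges:
        key = frozenset((u, v))
        assert len(key) == 2, f"self-loop ({u}, {v})"
        assert key not in seen, f"duplicate edge ({u}, {v})"
        seen.add(key)
    return seen


def binom_gof_pvalue(samples, trials, p):
    """Chi-square goodness-of-fit p-value of integer samples vs Binomial(trials, p).

    Bins the full support 0..trials into groups with expected count >= 5.
    """
    samples = np.asarray(samples)
    nreps = samples.size
    counts = Counter(samples.tolist())
    probs = stats.binom.pmf(np.arange(trials + 1), trials, p)
    obs_bins, exp_bins = [], []
    obs_acc = exp_acc = 0.0
    for k in range(trials + 1):
        obs_acc += counts.get(k, 0)
        exp_acc += probs[k] * nreps
        if exp_acc >= 5:
            obs_bins.append(obs_acc)
            exp_bins.append(exp_acc)
            obs_acc = exp_acc = 0.0
    # fold any light tail into the last bin
    if exp_acc > 0 or obs_acc > 0:
        if exp_bins:
            obs_bins[-1] += obs_acc
            exp_bins[-1] += exp_acc
        else:
            obs_bins.append(obs_acc)
            exp_bins.append(exp_acc)
    assert len(exp_bins) >= 2, "degenerate binning"
    return stats.chisquare(obs_bins, exp_bins).pvalue


def two_sample_count_pvalue(a, b):
    """Two-sample chi-square p-value that two integer samples share a distribution."""
    a, b = list(a), list(b)
    support = sorted(set(a) | set(b))
    ca, cb = Counter(a), Counter(b)
    cols = [np.array([ca.get(k, 0), cb.get(k, 0)], dtype=float) for k in support]
    merged = [cols[0]]
    for col in cols[1:]:  # pool sparse outcome classes so expected counts stay sane
        if merged[-1].sum() < 20:
            merged[-1] = merged[-1] + col
        else:
            merged.append(col)
    if merged[-1].sum() < 20 and len(merged) > 1:
        merged[-2] = merged[-2] + merged.pop()
    table = np.column_stack(merged)
    return stats.chi2_contingency(table).pvalue
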