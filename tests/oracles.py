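"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available (plain
loops, scipy reference routines, exhaustive enumeration) so that the package
implementations are checked against an independent route.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy import stats


def oracle_best_split(x: np.ndarray, min_markers: int):
    """Exhaustive best split by looping scipy t-tests over all candidates.

    Applies the same relative tolerance for degenerate (constant) data as the
    implementation so both routes agree on what counts as zero.
    """
    n = len(x)
    if n < 2 * min_markers:
        return None
    atol = 1e-10 * max(1.0, float(np.max(np.abs(x))))
    best = None
    for k in range(min_markers, n - min_markers + 1):
        left, right = x[:k], x[k:]
        diff = left.mean() - right.mean()
        if abs(diff) < atol:
            diff = 0.0
        ssw = (((left - left.mean()) ** 2).sum()
               + ((right - right.mean()) ** 2).sum())
        pooled_var = ssw / (n - 2)
        if pooled_var < atol * atol:
            pooled_var = 0.0
        if pooled_var == 0.0:
            if diff == 0.0:
                continue
            t_abs, p, snr = np.inf, 0.0, np.inf
        else:
            res = stats.ttest_ind(left, right, equal_var=True)
            t_abs, p = abs(float(res.statistic)), float(res.pvalue)
            snr = abs(diff) / np.sqrt(pooled_var)
        if best is None or t_abs > best[1]:
            best = (k, t_abs, p, snr)
    return best


def oracle_segment(x: np.ndarray, p_threshold: float, min_markers: int,
                   signal_noise_min: float) -> list[int]:
    """Exhaustive-search recursive segmentation with the same acceptance rule
    (p < threshold, both sides >= min_markers, |mean diff|/pooled SD >= s/n),
    implemented with plain loops and scipy."""
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        found = oracle_best_split(x[lo:hi], min_markers)
        if found is None:
            return
        k, _, p, snr = found
        if p < p_threshold and snr >= signal_noise_min:
            breakpoints.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, len(x))
    return sorted(breakpoints)


def oracle_fisher_rx2(table: np.ndarray) -> float:
    """Exact conditional p of an r x 2 table by enumerating every assignment
    of the pooled row categories to column 1 (sample-level combinatorics).

    Each of the C(N, c0) subsets of the pooled items is equally likely under
    fixed margins; the p-value is the fraction of subsets whose induced table
    is no more probable (has no larger multiplicity) than the observed one.
    """
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    c0 = int(t[:, 0].sum())
    items = np.repeat(np.arange(len(rows)), rows)
    counts: Counter = Counter()
    for subset in itertools.combinations(range(len(items)), c0):
        key = tuple(np.bincount(items[list(subset)], minlength=len(rows)))
        counts[key] += 1
    observed = tuple(int(v) for v in t[:, 0])
    obs_count = counts[observed]
    total = sum(counts.values())
    hits = sum(c for key, c in counts.items() if c <= obs_count)
    return hits / total


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up: min over j >= i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adjusted[order[rank - 1]] = running
    return adjusted


def oracle_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation as Pearson on average ranks, by hand."""

    def average_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = average_ranks(np.asarray(x)), average_ranks(np.asarray(y))
    return float(np.corrcoef(rx, ry)[0, 1])
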