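"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity from first principles (explicit
sorting, enumeration, linear scans, closed forms) without calling the
implementation under test, so agreement is evidence of correctness rather
than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def percentile_oracle(values, p):
    """Sort + linear interpolation with inclusive endpoints."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = p / 100.0 * (n - 1)
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def fs_tail_score_oracle(value, c0, c1, c2):
    """Explicit bin scan for the one-sided FS-tail rule."""
    for score, cut in ((0, c0), (1, c1), (2, c2)):
        if value <= cut:
            return score
    return 3


def bidirectional_score_oracle(value, cuts, lower_is_worse):
    """Interval-by-interval scan of the bidirectional map."""
    p5, p25, p75, p95 = cuts["p5"], cuts["p25"], cuts["p75"], cuts["p95"]
    lo, hi = cuts["min"], cuts["max"]
    if lower_is_worse:
        adverse = [(p5, p25, 1), (lo, p5, 2)]  # [lower, upper) intervals below p25
        if p25 <= value <= p75:
            return 0
        if value < p25:
            if value >= p5:
                return 1
            if value >= lo:
                return 2
            return 3
        # protective side
        return 0 if value <= p95 else 1
    else:
        if p25 <= value <= p75:
            return 0
        if value > p75:
            if value <= p95:
                return 1
            if value <= hi:
                return 2
            return 3
        return 0 if value >= p5 else 1


def startle_score_oracle(value, gate, c1, c2, higher_is_worse):
    if higher_is_worse:
        if value < gate:
            return 0
        if value <= c1:
            return 1
        if value <= c2:
            return 2
        return 3
    if value > gate:
        return 0
    if value >= c1:
        return 1
    if value >= c2:
        return 2
    return 3


def rle_oracle(seq, state):
    """Run-length encode by explicit iteration."""
    runs = []
    start = None
    for i, s in enumerate(seq):
        if s == state and start is None:
            start = i
        elif s != state and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(seq) - start))
    return runs


def latency_oracle(seq, state, epoch_seconds, min_seconds):
    need = int(round(min_seconds / epoch_seconds))
    for start, length in rle_oracle(seq, state):
        if length >= need:
            return start * epoch_seconds / 60.0
    return None


def midranks(values):
    """Average ranks computed by explicit tie-group scanning."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    """Tie-corrected H from the textbook rank-sum formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start:start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def friedman_oracle(mat):
    """Tie-free Friedman chi-square from the classic column-rank-sum form."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    ranks = np.array([midranks(list(row)) for row in mat])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float(np.sum(rj**2)) - 3.0 * n * (k + 1)


def signed_rank_exact_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    absd = [abs(x) for x in d]
    ranks = midranks(absd)
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    total = sum(ranks)
    dist = {}
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        dist[w] = dist.get(w, 0) + 1
    m = 2**n
    a = min(w_obs, total - w_obs)
    p = sum(c for w, c in dist.items() if w <= a or w >= total - a) / m
    return min(1.0, p)


def spearman_oracle(x, y):
    """Pearson correlation of midranks."""
    rx = np.array(midranks(list(x)))
    ry = np.array(midranks(list(y)))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def stationary_oracle(matrix, power=20000):
    """Long-run law by brute-force matrix powering."""
    p = np.linalg.matrix_power(np.asarray(matrix, dtype=float), power)
    return p[0]
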