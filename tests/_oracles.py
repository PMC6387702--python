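"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code path with the
package: midranks are built by explicit tie-group averaging, hypergeometric
tails by exact integer binomial-coefficient sums, and tiny linkages by
exhaustive greedy agglomeration over explicit cluster lists.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def midranks(values) -> np.ndarray:
    """Average ranks (1-based) with explicit tie-group handling."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return np.array(ranks)


def rank_then_pearson(x, y) -> float:
    """Spearman via explicit midranks followed by the Pearson formula."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by an exact integer sum of point masses."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def hypergeom_pmf_enum(N: int, K: int, n: int, k: int) -> float:
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def average_linkage_brute(points: np.ndarray):
    """Greedy average-linkage agglomeration over explicit cluster member lists.

    Returns the merge sequence [(members_a, members_b, distance), ...] with
    cluster members given as sorted tuples of original row indices.
    """
    points = np.asarray(points, dtype=float)
    clusters = [(i,) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dsum = 0.0
            for i in clusters[a]:
                for j in clusters[b]:
                    dsum += float(np.linalg.norm(points[i] - points[j]))
            d = dsum / (len(clusters[a]) * len(clusters[b]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return merges
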