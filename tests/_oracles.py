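"""Independent brute-force oracles the implementation is checked against.

Deliberately written with explicit loops and first-principles formulas, not
by calling the code under test.
"""

from __future__ import annotations

import math

import numpy as np


def moments_threshold_oracle(histogram) -> int:
    """Moment-preserving threshold by explicit moment bookkeeping and a scan
    over all cut points for the first cumulative fraction reaching the
    closed-form background fraction."""
    h = [float(v) for v in histogram]
    total = sum(h)
    p = [v / total for v in h]
    m1 = sum(i * p[i] for i in range(256))
    m2 = sum(i * i * p[i] for i in range(256))
    m3 = sum(i * i * i * p[i] for i in range(256))
    cd = m2 - m1 * m1
    if cd <= 1e-12:
        for i in range(256):
            if h[i] > 0:
                return i
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    csum = 0.0
    for t in range(256):
        csum += p[t]
        if csum >= p0 - 1e-9:
            return t
    return 255


def ranks_by_counting(values) -> list[float]:
    """Mid-ranks computed by pairwise comparison counting (no sorting library)."""
    n = len(values)
    ranks = []
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def kruskal_h_oracle(groups) -> float:
    """Tie-corrected Kruskal–Wallis H from the definition."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = ranks_by_counting(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for k, g in enumerate(groups):
        rsum = sum(ranks[offsets[k] : offsets[k + 1]])
        h += rsum * rsum / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t**3 - t
    denom = 1.0 - ties / (n**3 - n)
    if denom == 0:
        return 0.0
    return h / denom


def dunn_z_oracle(groups, i: int, j: int) -> float:
    """Dunn z for one pair from mean ranks, the stated variance, tie term."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = ranks_by_counting(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        sum(ranks[offsets[k] : offsets[k + 1]]) / len(g) for k, g in enumerate(groups)
    ]
    ties = sum(pooled.count(v) ** 3 - pooled.count(v) for v in set(pooled))
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    se = math.sqrt(var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
    if se == 0:
        return 0.0
    return (mean_ranks[i] - mean_ranks[j]) / se


def bin_overlap_oracle(n_src: int, n_bins: int, lo: float, hi: float) -> list[float]:
    """Fraction of each area-weighted bin covered by the interval [lo, hi)."""
    width = n_src / n_bins
    out = []
    for b in range(n_bins):
        b0, b1 = b * width, (b + 1) * width
        out.append(max(0.0, min(b1, hi) - max(b0, lo)) / width)
    return out
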