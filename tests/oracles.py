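"""Independent naive reference implementations used only by the tests.

Each oracle recomputes a quantity by brute force (enumeration, closed
form, O(n^3) agglomeration) without touching the package's code paths, so
agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def hypergeom_tail_enumerated(n_universe: int, n_a: int, n_b: int, k: int) -> float:
    """P(overlap >= k) by exhaustively enumerating every size-n_a draw.

    The top-n_b set is fixed to {0..n_b-1}; every C(N, n_a) subset is
    generated and its overlap counted.  Feasible for N <= 12.
    """
    marked = set(range(n_b))
    hits = total = 0
    for draw in itertools.combinations(range(n_universe), n_a):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_closed_form(n_universe: int, n_a: int, n_b: int, k: int) -> float:
    """P(overlap >= k) by summing the hypergeometric pmf with exact
    integer binomials."""
    denom = comb(n_universe, n_a)
    total = 0
    for x in range(k, min(n_a, n_b) + 1):
        if n_a - x <= n_universe - n_b:
            total += comb(n_b, x) * comb(n_universe - n_b, n_a - x)
    return total / denom


def fisher_greater_enumerated(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for the 2x2 table [[a,b],[c,d]] by
    summing exact hypergeometric terms over all overlaps >= a."""
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = comb(n, col)
    total = 0
    for x in range(a, min(row, col) + 1):
        if col - x <= n - row:
            total += comb(row, x) * comb(n - row, col - x)
    return total / denom


def naive_match_score(logfc: dict, up: set, down: set) -> float:
    """Per-gene loop version of the molecular match score."""
    m = 0.0
    for g, v in logfc.items():
        if g in up:
            m += v
        elif g in down:
            m -= v
    return m


def naive_average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of average-linkage agglomeration, O(n^3).

    Cluster distance = mean of all pairwise original distances between
    members (UPGMA on an arbitrary dissimilarity).  Returns heights in
    merge order (nondecreasing).
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def venn_regions_enumerated(named_sets: dict) -> dict[frozenset, int]:
    """Exclusive Venn-region counts by per-gene membership enumeration."""
    all_genes = set().union(*named_sets.values())
    counts: dict[frozenset, int] = {}
    for g in all_genes:
        member = frozenset(n for n, s in named_sets.items() if g in s)
        counts[member] = counts.get(member, 0) + 1
    return counts
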