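"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the library code paths they verify: tail
probabilities by exhaustive draw enumeration, ancestors by repeated
edge-following, associations by a pure-python all-pairs scan.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def enumerate_tail(N: int, n: int, K: int, i: int) -> float:
    """P(at least i annotated genes in a draw of n from N, K annotated),
    by enumerating every C(N, n) draw. Exact rational arithmetic."""
    annotated = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if len(set(draw) & annotated) >= i
    )
    return float(Fraction(hits, math.comb(N, n)))


def summed_tail(N: int, n: int, K: int, i: int) -> float:
    """Same tail via the explicit binomial sum with exact integers."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for k in range(i, min(n, K) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return float(total)


def augmented_series(N: int, n: int, K: int, i: int, r: int) -> float:
    """The augmented tail summed literally with exact integer arithmetic:
    sum_{k=i}^{min(n+r,K)} C(K, k+r) C(N-K, n-k) / C(N, n+r)."""
    denom = math.comb(N, n + r)
    total = Fraction(0)
    for k in range(i, min(n + r, K) + 1):
        if k + r > K or k > n or n - k < 0:
            continue
        total += Fraction(math.comb(K, k + r) * math.comb(N - K, n - k), denom)
    return float(total)


def ancestors_by_edge_following(edges: list[tuple[str, str]], term: str) -> set[str]:
    """All proper ancestors of ``term`` by naive repeated edge-following
    over child->parent edge pairs until a fixed point."""
    found: set[str] = set()
    frontier = {term}
    while frontier:
        step = {p for (c, p) in edges if c in frontier}
        new = step - found
        found |= new
        frontier = new
    return found


def brute_force_associations(lncrnas, genes, window_bp: int) -> set[tuple[str, str, int]]:
    """(lncrna_id, gene_id, distance) for every same-chromosome pair with
    span distance <= window, by scanning all pairs in pure python."""
    out = set()
    for lnc in lncrnas:
        for gene in genes:
            if lnc.chrom != gene.chrom:
                continue
            if lnc.start <= gene.end and gene.start <= lnc.end:
                dist = 0
            elif lnc.end < gene.start:
                dist = gene.start - lnc.end
            else:
                dist = lnc.start - gene.end
            if dist <= window_bp:
                out.add((lnc.feature_id, gene.feature_id, dist))
    return out
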