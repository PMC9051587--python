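"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from itertools import combinations


def exhaustive_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every size-n draw from a population of N
    items of which the first K are successes. Exact (rational arithmetic)."""
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        successes = sum(1 for x in draw if x < K)
        if successes >= k:
            hits += 1
    return Fraction(hits, total)


def tail_counts_by_K(N: int, n: int) -> dict[int, list[int]]:
    """For each K in 0..N, the number of size-n draws with >= k successes,
    indexed by k. One enumeration pass shared across all K."""
    # histogram[K][s] = number of draws with exactly s successes when the
    # first K items are the successes
    hist = {K: [0] * (n + 1) for K in range(N + 1)}
    for draw in combinations(range(N), n):
        sorted_draw = sorted(draw)
        for K in range(N + 1):
            s = sum(1 for x in sorted_draw if x < K)
            hist[K][s] += 1
    out = {}
    for K, h in hist.items():
        tails = [0] * (n + 2)
        for s in range(n, -1, -1):
            tails[s] = tails[s + 1] + h[s]
        out[K] = tails[: n + 1]
    return out


def bh_bruteforce(pvalues: list[float]) -> list[float]:
    """BH adjusted p-values from the literal min-over-suffix definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted_sorted = [0.0] * m
    for rank_idx in range(m):
        suffix = [
            min(1.0, pvalues[order[j]] * m / (j + 1)) for j in range(rank_idx, m)
        ]
        adjusted_sorted[rank_idx] = min(suffix)
    out = [0.0] * m
    for rank_idx, orig in enumerate(order):
        out[orig] = adjusted_sorted[rank_idx]
    return out
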