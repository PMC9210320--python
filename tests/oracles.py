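"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^2) scans, full enumerations,
hand-written formulas — and shares no code with the package internals it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def collapse_oracle(counts: dict[str, int], distance: int,
                    ratio: float) -> tuple[dict[str, int], dict[str, int]]:
    """All-pairs Hamming elimination: dominated barcodes removed."""
    barcodes = list(counts)
    retained, eliminated = {}, {}
    for bc in barcodes:
        dominated = any(
            other != bc and hamming(bc, other) <= distance
            and counts[other] >= ratio * counts[bc]
            for other in barcodes
        )
        (eliminated if dominated else retained)[bc] = counts[bc]
    return retained, eliminated


def collapse_two_stage_oracle(counts: dict[str, int], ratio: float) -> set[str]:
    kept1, _ = collapse_oracle(counts, 1, ratio)
    kept2, _ = collapse_oracle(kept1, 2, ratio)
    return set(kept2)


def junction_oracle(read: str, arm: str, max_mismatches: int,
                    barcode_length: int, barcode_gap: int,
                    min_fragment_length: int):
    """Sliding-window scan for the arm's final 22-mer; leftmost hit wins.

    Returns (barcode, fragment) or None.
    """
    probe = arm[-22:]
    for offset in range(len(read) - 22 + 1):
        if hamming(read[offset:offset + 22], probe) <= max_mismatches:
            bc_end = offset - barcode_gap
            bc_start = bc_end - barcode_length
            fragment = read[offset + 22:]
            if bc_start < 0 or len(fragment) < min_fragment_length:
                return None
            return read[bc_start:bc_end], fragment
    return None


def barcode_extract_oracle(read: str, up: str, down: str,
                           barcode_length: int, max_mismatches: int):
    """Leftmost up-flank match with mismatches, then verify down-flank."""
    for offset in range(len(read) - len(up) + 1):
        if hamming(read[offset:offset + len(up)], up) <= max_mismatches:
            start = offset + len(up)
            end = start + barcode_length
            if end + len(down) > len(read):
                return None
            if hamming(read[end:end + len(down)], down) <= max_mismatches:
                return read[start:end]
            return None
    return None


def mannwhitney_exact_oracle(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Enumerates every C(n+m, n) relabelling of the pooled values; the
    two-sided p is the probability of a U at least as far from the null
    mean nm/2 as the observed one.
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = x + y

    def u_stat(group_x):
        group_y = [v for i, v in enumerate(pooled) if i not in set(group_x)]
        return sum(1 for a in (pooled[i] for i in group_x) for b in group_y if a > b) \
            + 0.5 * sum(1 for a in (pooled[i] for i in group_x) for b in group_y if a == b)

    u_obs = sum(1 for a in x for b in y if a > b) + \
        0.5 * sum(1 for a in x for b in y if a == b)
    center = n * m / 2
    count = total = 0
    for idx in combinations(range(n + m), n):
        u = u_stat(idx)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


def bh_oracle(p_values) -> list[float]:
    """Benjamini-Hochberg by the textbook formula: sort, scale, cummin, clip."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p_values[i] * n / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def hypergeom_tail_ge(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k), X ~ Hypergeom(N population, K marked, n draws)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(total - col1, row1 - x)
                / math.comb(total, row1))

    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def subset_enum_effectsize_oracle(abs_effects: dict[str, float],
                                  members: set[str]) -> float:
    """Exact p for the median-|effect| test by enumerating all same-size subsets."""
    genes = sorted(abs_effects)
    k = len(members)
    e_true = median([abs_effects[g] for g in members])
    count = total = 0
    for subset in combinations(genes, k):
        total += 1
        if median([abs_effects[g] for g in subset]) >= e_true - 1e-12:
            count += 1
    return count / total


def subset_enum_interaction_oracle(edges: set[frozenset], genome: list[str],
                                   k: int, r_true: float) -> float:
    """Exact p for the internal-edge-ratio test over all C(|genome|, k) subsets."""
    count = total = 0
    for subset in combinations(sorted(genome), k):
        s = set(subset)
        touching = [e for e in edges if e & s]
        r = (sum(1 for e in touching if e <= s) / len(touching)) if touching else 0.0
        total += 1
        if r >= r_true - 1e-12:
            count += 1
    return count / total


def median(values):
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2
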