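"""Damerau-Levenshtein distance (optimal string alignment variant).

Counts single-character insertions, deletions, substitutions and adjacent
transpositions.  Pure-Python; strings in this package are short (binomial
names), so the O(|a||b|) rolling-row DP is plenty fast.
"""

from __future__ import annotations


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance between *a* and *b* with adjacent transpositions."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            best = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and ca == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                best = min(best, prev2[j - 2] + 1)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


def normalized_similarity(a: str, b: str) -> float:
    """``1 - DL(a, b) / max(len(a), len(b))``; equals 1.0 iff ``a == b``."""
    if a == b:
        return 1.0
    denom = max(len(a), len(b))
    if denom == 0:
        return 1.0
    return 1.0 - damerau_levenshtein(a, b) / denom
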