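"""Independent reference implementations used only by tests.

These are deliberately written in a different style from the production
code (numpy full-matrix / memoized recursion) so a shared bug is
unlikely.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(20000)  # dl_oracle recursion on longer strings


def sw_score_oracle(a: str, b: str, match: int = 2, mismatch: int = -1,
                    gap: int = -1) -> int:
    """Brute-force Smith-Waterman: fill the full matrix, return the max."""
    H = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int64)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    return int(H.max())


def dl_oracle(a: str, b: str) -> int:
    """Memoized-recursion Damerau-Levenshtein (optimal string alignment)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def nearest_records(table, query: str) -> tuple[int, set[str]]:
    """Exhaustive scan: minimum DL distance and the ids achieving it."""
    best = None
    ids: set[str] = set()
    for rec in table:
        dist = dl_oracle(query, rec.canonical_name)
        if best is None or dist < best:
            best, ids = dist, {rec.record_id}
        elif dist == best:
            ids.add(rec.record_id)
    return best, ids
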