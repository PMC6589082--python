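"""Independent brute-force oracles used to validate the search engines.

Everything here is deliberately naive — textbook recursions and exhaustive
enumeration — and shares no code with the implementation under test.
"""

from functools import lru_cache
from itertools import product


def lev_distance(a: str, b: str) -> int:
    """Textbook Levenshtein distance (full matrix, no pruning)."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j - 1] + cost, d[i - 1][j] + 1, d[i][j - 1] + 1)
    return d[la][lb]


def osa_distance(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j - 1] + cost, d[i - 1][j] + 1, d[i][j - 1] + 1)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def semi_global_matches(P: str, T: str, k: int, dist=lev_distance) -> set[tuple[int, int]]:
    """All (end, edits) pairs where some substring of T ending at `end` is
    within k edits of P — edits being the minimum over start positions."""
    out = set()
    for end in range(len(T) + 1):
        best = min(dist(P, T[s:end]) for s in range(end + 1))
        if best <= k:
            out.add((end, best))
    return out


def hamming_matches(P: str, T: str, k: int) -> set[tuple[int, int]]:
    """All (end, mismatches) for full-length windows of T within k mismatches."""
    m = len(P)
    out = set()
    for s in range(len(T) - m + 1):
        e = sum(1 for i in range(m) if T[s + i] != P[i])
        if e <= k:
            out.add((s + m, e))
    return out


def enumerate_segmentations(patterns, text: str) -> bool:
    """Can `patterns` tile `text` into contiguous in-order runs?  Each pattern
    is a (min_len, max_len, allowed) triple; allowed=None means any char.
    Pure recursion over every split point."""

    def ok(seg: str, allowed) -> bool:
        return allowed is None or all(c in allowed for c in seg)

    def rec(pi: int, ti: int) -> bool:
        if pi == len(patterns):
            return ti == len(text)
        mn, mx, allowed = patterns[pi]
        hi = len(text) - ti if mx is None else min(mx, len(text) - ti)
        for take in range(mn, hi + 1):
            seg = text[ti:ti + take]
            if ok(seg, allowed) and rec(pi + 1, ti + take):
                return True
        return False

    return rec(0, 0)


def naive_interval_recursion(patterns, text: str) -> bool:
    """The cubic sum-over-split-points recursion for interval chunks, with
    memoization but no prefix sums or run-length tables."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if j == 0:
            return 1 if i == 0 else 0
        mn, mx, allowed = patterns[j - 1]
        hi = i - mn
        lo = 0 if mx is None else i - mx
        total = 0
        for kk in range(max(lo, 0), hi + 1):
            seg = text[kk:i]
            if allowed is not None and any(c not in allowed for c in seg):
                continue
            total += f(kk, j - 1)
        return total

    return f(len(text), len(patterns)) != 0


def all_strings(alphabet: str, max_len: int, min_len: int = 0):
    """Every string over `alphabet` with length in [min_len, max_len]."""
    for L in range(min_len, max_len + 1):
        for tup in product(alphabet, repeat=L):
            yield "".join(tup)
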