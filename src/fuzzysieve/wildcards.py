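"""Wildcard pattern matching.

Fixed-length wildcard patterns are checked with a sliding window: the pattern
matches at a position iff the next ``length`` characters are all in its
character class.

Chains of consecutive interval-length wildcard patterns are matched together:
the patterns must partition a text segment into contiguous, non-overlapping,
in-order runs, each run's length inside the pattern's ``[min, max]`` interval
and each character allowed by the pattern's class.  Writing ``f(i, j)`` for
"the first ``j`` patterns can tile the first ``i`` segment characters", the
naive recursion sums ``f(k, j-1)`` over every admissible split point ``k``
and re-checks the character run, which is cubic in the segment length.  Two
standard tricks make it ``O(|patterns| * length)``:

* ``l(i, j)`` — the longest run of characters allowed by pattern ``j`` that
  ends at position ``i`` (one incremental update per cell);
* ``p(i, j)`` — prefix sums of ``f(i, j)`` so any window of split points is
  summed in constant time.

giving ``f(i, j) = p(i - min_j, j-1) - p(max(i - max_j, i - l(i, j)) - 1,
j-1)`` with out-of-range prefix-sum indices contributing zero.  ``f`` is
stored saturated to {0, 1} — only ``f != 0`` is ever queried, and saturation
keeps the prefix sums small.

The tables belong to an :class:`IntervalDPState` anchored at a fixed text
index.  The greedy line matcher probes many candidate end positions for the
same anchor, so the state extends its frontier incrementally: rows computed
earlier are never recomputed or changed.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

from .errors import MatchError, TemplateError
from .patterns import FixedWildcardPattern, IntervalPattern, ValueExpr
from .variables import VariableStore


def resolve_length(pattern: FixedWildcardPattern, vars: Optional[VariableStore]) -> int:
    """Resolve a fixed-length pattern's length, following a variable
    reference when needed."""
    length: Union[int, ValueExpr] = pattern.length
    if isinstance(length, int):
        return length
    if vars is None:
        raise MatchError(
            f"length of pattern references %{length.payload}% but no "
            "variables are available"
        )
    value = vars.lookup(length.payload)
    if not isinstance(value, int):
        raise TemplateError(
            f"length reference %{length.payload}% resolved to non-integer {value!r}"
        )
    if value < 1:
        raise TemplateError(
            f"length reference %{length.payload}% resolved to {value} (< 1)"
        )
    return value


def match_fixed(
    pattern: FixedWildcardPattern,
    T: str,
    at: int,
    vars: Optional[VariableStore] = None,
) -> bool:
    """True iff ``T[at : at+length]`` fits in the line and every character is
    allowed by the pattern's class."""
    L = resolve_length(pattern, vars)
    if at < 0 or at + L > len(T):
        return False
    cls = pattern.char_class
    if cls.is_universal:
        return True
    return all(c in cls for c in T[at:at + L])


class IntervalDPState:
    """Incremental f/p/l tables for one interval-pattern chunk.

    The chunk is anchored at text index ``anchor``; row ``i`` of the tables
    describes the segment ``T[anchor : anchor+i]``.  Queries at any end up to
    the current frontier are O(1); extending the frontier fills new rows only.
    An empty pattern list matches exactly the empty segment.
    """

    def __init__(self, patterns: Sequence[IntervalPattern], T: str, anchor: int):
        if not 0 <= anchor <= len(T):
            raise MatchError(f"anchor {anchor} outside text of length {len(T)}")
        self.patterns = tuple(patterns)
        self.T = T
        self.anchor = anchor
        m = len(self.patterns)
        # row 0: empty segment
        f0 = [1] + [0] * m
        for j in range(1, m + 1):
            if self.patterns[j - 1].min_len == 0:
                f0[j] = f0[j - 1]
        self._f: list[list[int]] = [f0]
        self._p: list[list[int]] = [list(f0)]
        self._l: list[list[int]] = [[0] * (m + 1)]

    @property
    def frontier(self) -> int:
        """Highest text index (absolute) with computed rows."""
        return self.anchor + len(self._f) - 1

    def extend_frontier(self, new_frontier: int) -> None:
        """Fill tables up to absolute text index ``new_frontier``; previously
        computed rows are untouched."""
        if new_frontier > len(self.T):
            raise MatchError(
                f"frontier {new_frontier} beyond text length {len(self.T)}"
            )
        m = len(self.patterns)
        f, p, l = self._f, self._p, self._l
        for i in range(len(f), new_frontier - self.anchor + 1):
            ch = self.T[self.anchor + i - 1]
            lrow = [0] * (m + 1)
            frow = [0] * (m + 1)
            prow = [0] * (m + 1)
            lprev = l[i - 1]
            pprev = p[i - 1]
            prow[0] = pprev[0]  # f(i, 0) = 0 for i >= 1
            for j in range(1, m + 1):
                pat = self.patterns[j - 1]
                lj = lprev[j] + 1 if ch in pat.char_class else 0
                lrow[j] = lj
                hi = i - pat.min_len
                if hi >= 0:
                    lo = i - pat.max_len if pat.max_len is not None else 0
                    if i - lj > lo:
                        lo = i - lj  # runs longer than l(i, j) contain a bad char
                    if lo <= hi:
                        # sum of f(lo..hi, j-1) via prefix sums; row i of p is
                        # the one being built (needed when hi == i, a
                        # zero-length match of pattern j)
                        hi_row = prow if hi == i else p[hi]
                        total = hi_row[j - 1]
                        if lo >= 1:
                            total -= p[lo - 1][j - 1]
                        if total > 0:
                            frow[j] = 1
                prow[j] = pprev[j] + frow[j]
            f.append(frow)
            p.append(prow)
            l.append(lrow)

    def matches(self, end: int) -> bool:
        """True iff the chunk's patterns tile ``T[anchor:end]`` (absolute
        ``end``); extends the frontier as needed."""
        if end < self.anchor:
            return False
        if end > self.frontier:
            self.extend_frontier(end)
        return self._f[end - self.anchor][len(self.patterns)] != 0


def match_interval_chunk(
    patterns: Sequence[IntervalPattern],
    T: str,
    start: int,
    end: int,
) -> bool:
    """One-shot convenience: do ``patterns`` tile ``T[start:end]``?"""
    return IntervalDPState(patterns, T, start).matches(end)
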