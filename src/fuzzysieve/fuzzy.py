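"""Approximate occurrence search for fuzzy subpatterns.

Three metrics are supported:

* **Levenshtein** — unit-cost insertions, deletions, substitutions, found with
  the classic semi-global recurrence ``d(i,0)=0``, ``d(0,j)=j``,
  ``d(i,j)=d(i-1,j-1)`` on a character match else
  ``1+min(d(i-1,j-1), d(i-1,j), d(i,j-1))``, where ``d(i,j)`` is the distance
  between the pattern prefix ``P[1..j]`` and the best-matching suffix of
  ``T[1..i]``.  The expected cost drops from ``O(|P||T|)`` to ``O(k|T|)``
  with Ukkonen's cutoff, which tracks the deepest row still within the edit
  budget; the cutoff never changes the result set.
* **restricted Damerau–Levenshtein** (optimal string alignment) — the same DP
  plus unit-cost adjacent transpositions, each character taking part in at
  most one transposition.
* **Hamming** — substitutions only, via the Bitap shift-and algorithm with
  ``k+1`` state vectors, ``O(k · |T| · ceil(|P|/w))`` worst case for word
  width ``w``.  Masks and state vectors are genuinely split into
  ``ceil(|P|/w)`` machine words.

Matches report one candidate per end position: the minimal edit count at that
end, with the start recovered by traceback preferring diagonal over vertical
(text-consuming) over horizontal (pattern-consuming) moves.

Subpatterns are pre-eliminated with overlapping n-grams: a subpattern whose
length ``|P|`` satisfies ``|P| > (k+1)(n-1)+k`` must share at least one
n-gram with any text window within ``k`` edits, so it can be dropped when
none of its n-grams occurs in the text.  The largest usable size is the
greatest ``n`` with ``n < (|P|-k)/(k+1)+1``; multiple subpatterns use the
minimum of their individual maxima.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .errors import MatchError
from .patterns import DEFAULT_WILDCARDS, FuzzyPattern, Subpattern

_INF = 1 << 30

#: Word width used by the Hamming searcher unless overridden.
DEFAULT_WORD_WIDTH = 63


@dataclass(frozen=True)
class FuzzyMatch:
    """One candidate occurrence of a subpattern in a text line.

    ``start``/``end`` are 0-based half-open text indices; ``edits`` counts
    the edits of the best alignment ending at ``end``.
    """

    subpattern_idx: int
    start: int
    end: int
    edits: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "FuzzyMatch":
        if offset == 0:
            return self
        return FuzzyMatch(self.subpattern_idx, self.start + offset,
                          self.end + offset, self.edits)


# ---------------------------------------------------------------------------
# edit-distance DP (Levenshtein / restricted Damerau-Levenshtein)


def _iter_dp_matches(
    P: Subpattern,
    T: str,
    k: int,
    *,
    transpositions: bool,
    overlap_start: bool,
    overlap_end: bool,
    min_overlap: int,
    wildcard_chars: frozenset[str],
    use_cutoff: bool,
    subpattern_idx: int,
) -> Iterator[FuzzyMatch]:
    seq = P.sequence
    wild = P.wildcard_positions
    m = len(seq)
    n = len(T)

    def char_match(ti: int, pj: int) -> bool:
        # ti, pj are 1-based DP indices
        return (pj - 1) in wild or T[ti - 1] in wildcard_chars \
            or T[ti - 1] == seq[pj - 1]

    # Alongside each distance cell d(i, j) we carry the smallest text start
    # index among the alignments achieving it, so every emitted match reports
    # the longest text span of its minimal-edit alignments — a greedy
    # traceback cannot guarantee that, and anchored templates depend on it.
    cols: list[list[int]] = []
    scols: list[list[int]] = []
    if overlap_start:
        col0 = [0] * (m + 1)
        la = m
    else:
        la = m if not use_cutoff else min(m, k)
        col0 = list(range(la + 1))
    cols.append(col0)
    scols.append([0] * len(col0))  # column 0 alignments start at text index 0

    def emit(i: int, j: int, edits: int, hang_end: int) -> Optional[FuzzyMatch]:
        start = scols[i][j]
        length = i - start
        if hang_end > 0 and length < min_overlap:
            return None
        if overlap_start and start == 0 and length < min_overlap:
            return None
        return FuzzyMatch(subpattern_idx, start, i, edits)

    # column i = 0 (end position 0)
    if overlap_end and n == 0:
        best = _best_overlap_row(col0, m, k)
        if best is not None:
            j, v = best
            mt = emit(0, j, v, m - j)
            if mt:
                yield mt
    elif m < len(col0) and col0[m] <= k:
        mt = emit(0, m, col0[m], 0)
        if mt:
            yield mt
    if n == 0:
        return

    for i in range(1, n + 1):
        lim = min(m, la + 1) if use_cutoff else m
        prev = cols[i - 1]
        sprev = scols[i - 1]
        plen = len(prev)
        prev2 = cols[i - 2] if transpositions and i > 1 else None
        sprev2 = scols[i - 2] if transpositions and i > 1 else None
        ncol = [0] * (lim + 1)
        nscol = [0] * (lim + 1)
        nscol[0] = i  # the empty alignment ending at i starts at i
        for j in range(1, lim + 1):
            pd = prev[j - 1] if j - 1 < plen else _INF
            dcost = pd if char_match(i, j) else pd + 1
            vcost = (prev[j] if j < plen else _INF) + 1
            hcost = ncol[j - 1] + 1
            tcost = _INF
            if (
                prev2 is not None and j > 1 and j - 2 < len(prev2)
                and _cross_match(seq, wild, T, wildcard_chars, i, j)
            ):
                tcost = prev2[j - 2] + 1
            best = dcost
            if vcost < best:
                best = vcost
            if hcost < best:
                best = hcost
            if tcost < best:
                best = tcost
            s = _INF
            if dcost == best and j - 1 < plen:
                s = sprev[j - 1]
            if vcost == best and j < plen and sprev[j] < s:
                s = sprev[j]
            if hcost == best and nscol[j - 1] < s:
                s = nscol[j - 1]
            if tcost == best and sprev2[j - 2] < s:
                s = sprev2[j - 2]
            ncol[j] = best
            nscol[j] = s
        cols.append(ncol)
        scols.append(nscol)
        if use_cutoff:
            la = lim
            while la > 0 and ncol[la] > k:
                la -= 1
        if i == n and overlap_end:
            best = _best_overlap_row(ncol, m, k)
            if best is not None:
                j, v = best
                mt = emit(i, j, v, m - j)
                if mt:
                    yield mt
        else:
            if m < len(ncol) and ncol[m] <= k:
                mt = emit(i, m, ncol[m], 0)
                if mt:
                    yield mt


def _cross_match(seq, wild, T, wildcard_chars, i, j):
    """Adjacent transposition applicability at DP cell (i, j), 1-based."""

    def cm(ti, pj):
        return (pj - 1) in wild or T[ti - 1] in wildcard_chars \
            or T[ti - 1] == seq[pj - 1]

    return cm(i, j - 1) and cm(i - 1, j)


def _best_overlap_row(col: Sequence[int], m: int, k: int) -> Optional[tuple[int, int]]:
    """Pick the row to end at when the pattern may overhang the text end:
    minimal edits, then the fewest overhanging characters."""
    best: Optional[tuple[int, int]] = None
    for j in range(min(m, len(col) - 1), -1, -1):
        v = col[j]
        if v <= k and (best is None or v < best[1]):
            best = (j, v)
    return best


def search_levenshtein(
    P: Subpattern,
    T: str,
    k: int,
    *,
    overlap_start: bool = False,
    overlap_end: bool = False,
    min_overlap: int = 1,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
    use_cutoff: bool = True,
    subpattern_idx: int = 0,
) -> list[FuzzyMatch]:
    """All approximate occurrences of ``P`` in ``T`` under Levenshtein
    distance, one per end position, in ascending end order."""
    return list(_iter_dp_matches(
        P, T, k, transpositions=False, overlap_start=overlap_start,
        overlap_end=overlap_end, min_overlap=min_overlap,
        wildcard_chars=wildcard_chars, use_cutoff=use_cutoff,
        subpattern_idx=subpattern_idx,
    ))


def search_damerau(
    P: Subpattern,
    T: str,
    k: int,
    *,
    overlap_start: bool = False,
    overlap_end: bool = False,
    min_overlap: int = 1,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
    use_cutoff: bool = True,
    subpattern_idx: int = 0,
) -> list[FuzzyMatch]:
    """As :func:`search_levenshtein`, with adjacent transpositions costing one
    edit (restricted / optimal-string-alignment variant)."""
    return list(_iter_dp_matches(
        P, T, k, transpositions=True, overlap_start=overlap_start,
        overlap_end=overlap_end, min_overlap=min_overlap,
        wildcard_chars=wildcard_chars, use_cutoff=use_cutoff,
        subpattern_idx=subpattern_idx,
    ))


# ---------------------------------------------------------------------------
# Bitap (Hamming)


def bitap_word_count(pattern_len: int, word_width: int = DEFAULT_WORD_WIDTH) -> int:
    """Number of machine words per mask/state vector: ``ceil(|P|/w)``."""
    return -(-pattern_len // word_width)


def build_bitap_masks(
    P: Subpattern,
    word_width: int = DEFAULT_WORD_WIDTH,
) -> tuple[dict[str, tuple[int, ...]], tuple[int, ...], tuple[int, ...]]:
    """Per-character bit masks split into ``ceil(|P|/w)`` words.

    Returns ``(masks, default_mask, full_mask)`` where ``default_mask`` covers
    characters absent from the pattern (wildcard positions only) and
    ``full_mask`` has every pattern-position bit set (for wildcard text
    characters).
    """
    m = len(P.sequence)
    W = bitap_word_count(m, word_width)
    per_char: dict[str, list[int]] = {}
    default = [0] * W
    full = [0] * W
    for pos in range(m):
        w_i, b_i = divmod(pos, word_width)
        bit = 1 << b_i
        full[w_i] |= bit
        if pos in P.wildcard_positions:
            default[w_i] |= bit
            for mask in per_char.values():
                mask[w_i] |= bit
        else:
            ch = P.sequence[pos]
            if ch not in per_char:
                per_char[ch] = list(default)
            per_char[ch][w_i] |= bit
    # characters seen later must still include earlier wildcard bits
    for mask in per_char.values():
        for w_i in range(W):
            mask[w_i] |= default[w_i]
    return (
        {c: tuple(v) for c, v in per_char.items()},
        tuple(default),
        tuple(full),
    )


def _shift1(words: Sequence[int], word_width: int, word_mask: int) -> list[int]:
    out = []
    carry = 1  # seed a fresh match start at position 1
    for w in words:
        out.append(((w << 1) | carry) & word_mask)
        carry = (w >> (word_width - 1)) & 1
    return out


def iter_hamming_matches(
    P: Subpattern,
    T: str,
    k: int,
    word_width: int = DEFAULT_WORD_WIDTH,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
    subpattern_idx: int = 0,
) -> Iterator[FuzzyMatch]:
    m = len(P.sequence)
    masks, default, full = build_bitap_masks(P, word_width)
    W = len(full)
    word_mask = (1 << word_width) - 1
    top_w, top_b = divmod(m - 1, word_width)
    R: list[list[int]] = [[0] * W for _ in range(k + 1)]
    for i, c in enumerate(T):
        cmask = full if c in wildcard_chars else masks.get(c, default)
        shifted = [_shift1(r, word_width, word_mask) for r in R]
        for e in range(k + 1):
            cur = [shifted[e][w] & cmask[w] for w in range(W)]
            if e > 0:
                prev = shifted[e - 1]
                cur = [cur[w] | prev[w] for w in range(W)]
            R[e] = cur
        for e in range(k + 1):
            if (R[e][top_w] >> top_b) & 1:
                yield FuzzyMatch(subpattern_idx, i + 1 - m, i + 1, e)
                break


def search_hamming_bitap(
    P: Subpattern,
    T: str,
    k: int,
    word_width: int = DEFAULT_WORD_WIDTH,
    *,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
    subpattern_idx: int = 0,
) -> list[FuzzyMatch]:
    """All length-``|P|`` windows of ``T`` with at most ``k`` mismatches."""
    return list(iter_hamming_matches(
        P, T, k, word_width, wildcard_chars, subpattern_idx,
    ))


# ---------------------------------------------------------------------------
# n-gram pre-elimination


def max_ngram_size(pattern_len: int, k: int) -> int:
    """Largest n-gram size usable to eliminate a length-``pattern_len``
    subpattern at ``k`` edits: the greatest ``n`` with
    ``n < (pattern_len - k)/(k + 1) + 1``; 0 when no positive size works."""
    n = -((pattern_len + 1) // -(k + 1)) - 1  # largest n with n(k+1) < L+1
    return n if n >= 1 else 0


def auto_ngram_size(subpatterns: Sequence[Subpattern], k: int) -> int:
    """Minimum over subpatterns of their maximum usable n-gram size; disabled
    (0) when any subpattern contains wildcard positions, since wildcards are
    invisible to n-grams."""
    if any(sp.wildcard_positions for sp in subpatterns):
        return 0
    return min(max_ngram_size(sp.length, k) for sp in subpatterns)


def ngram_filter(
    subpatterns: Sequence[Subpattern],
    T: str,
    k: int,
    n: int,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
) -> set[int]:
    """Indices of subpatterns that survive n-gram elimination against ``T``.

    A subpattern is eliminated only when ``|P| > (k+1)(n-1)+k`` holds *and*
    none of its n-grams occurs in ``T``.  Shorter subpatterns, subpatterns
    with wildcard positions, and all subpatterns when the text itself
    contains wildcard characters, always survive.
    """
    all_idx = set(range(len(subpatterns)))
    if n < 1:
        return all_idx
    if any(c in wildcard_chars for c in T):
        return all_idx
    threshold = (k + 1) * (n - 1) + k
    survivors: set[int] = set()
    for idx, sp in enumerate(subpatterns):
        if sp.length <= threshold or sp.wildcard_positions:
            survivors.add(idx)
            continue
        seq = sp.sequence
        if any(seq[i:i + n] in T for i in range(sp.length - n + 1)):
            survivors.add(idx)
    return survivors


# ---------------------------------------------------------------------------
# combined candidate streams


def _metric_iter(pattern: FuzzyPattern, sp: Subpattern, idx: int, text: str,
                 *, overlap_start: bool, use_cutoff: bool,
                 wildcard_chars: frozenset[str]) -> Iterator[FuzzyMatch]:
    if pattern.metric == "hamming":
        return iter_hamming_matches(
            sp, text, pattern.max_edits,
            wildcard_chars=wildcard_chars, subpattern_idx=idx,
        )
    return _iter_dp_matches(
        sp, text, pattern.max_edits,
        transpositions=(pattern.metric == "damerau"),
        overlap_start=overlap_start, overlap_end=pattern.overlap_end,
        min_overlap=pattern.min_overlap, wildcard_chars=wildcard_chars,
        use_cutoff=use_cutoff, subpattern_idx=idx,
    )


def iter_pattern_candidates(
    pattern: FuzzyPattern,
    T: str,
    from_index: int = 0,
    *,
    use_cutoff: bool = True,
    use_filter: bool = True,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
) -> Iterator[FuzzyMatch]:
    """Lazily yield candidates of all surviving subpatterns in
    ``T[from_index:]``, ordered by ascending end position, then ascending
    edits, then ascending subpattern index.  Coordinates are global (offsets
    into ``T``).  Overlap at the text start only applies when searching from
    the line start."""
    if pattern.subpatterns is None:
        raise MatchError("fuzzy pattern subpatterns not materialized")
    text = T[from_index:] if from_index else T
    subs = pattern.subpatterns
    if use_filter:
        n = pattern.ngram if isinstance(pattern.ngram, int) \
            else auto_ngram_size(subs, pattern.max_edits)
        surviving = ngram_filter(subs, text, pattern.max_edits, n, wildcard_chars)
    else:
        surviving = set(range(len(subs)))
    overlap_start = pattern.overlap_start and from_index == 0
    streams = [
        _metric_iter(pattern, subs[i], i, text, overlap_start=overlap_start,
                     use_cutoff=use_cutoff, wildcard_chars=wildcard_chars)
        for i in sorted(surviving)
    ]
    merged: Iterable[FuzzyMatch] = heapq.merge(
        *streams, key=lambda mt: (mt.end, mt.edits, mt.subpattern_idx),
    )
    for mt in merged:
        yield mt.shifted(from_index)


def best_subpattern_match(
    pattern: FuzzyPattern,
    T: str,
    from_index: int = 0,
    **kwargs,
) -> list[FuzzyMatch]:
    """Ordered candidate list (see :func:`iter_pattern_candidates`)."""
    return list(iter_pattern_candidates(pattern, T, from_index, **kwargs))


# ---------------------------------------------------------------------------
# anchored (prefix) matching, used for the tail of a fixed-length chunk


def anchored_matches(
    pattern: FuzzyPattern,
    T: str,
    at: int,
    *,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
) -> list[tuple[int, int, int]]:
    """Matches of any subpattern that start exactly at ``at``.

    Returns ``(edits, end, subpattern_idx)`` triples sorted ascending, i.e.
    lowest edit count first — the greedy rule for patterns matched
    consecutively after a chunk's starting pattern.  Unlike the semi-global
    search, alignments here are global in the text prefix: every character of
    ``T[at:end]`` is consumed.
    """
    if pattern.subpatterns is None:
        raise MatchError("fuzzy pattern subpatterns not materialized")
    k = pattern.max_edits
    out: list[tuple[int, int, int]] = []
    text = T[at:]
    for idx, sp in enumerate(pattern.subpatterns):
        if pattern.metric == "hamming":
            m = len(sp.sequence)
            if m <= len(text):
                e = sum(
                    1 for p in range(m)
                    if p not in sp.wildcard_positions
                    and text[p] not in wildcard_chars
                    and text[p] != sp.sequence[p]
                )
                if e <= k:
                    out.append((e, at + m, idx))
            continue
        out.extend(
            (e, at + i, idx)
            for e, i in _anchored_dp(sp, text, k,
                                     transpositions=(pattern.metric == "damerau"),
                                     overlap_end=pattern.overlap_end,
                                     min_overlap=pattern.min_overlap,
                                     wildcard_chars=wildcard_chars)
        )
    out.sort()
    return out


def _anchored_dp(sp: Subpattern, text: str, k: int, *, transpositions: bool,
                 overlap_end: bool, min_overlap: int,
                 wildcard_chars: frozenset[str]) -> list[tuple[int, int]]:
    """Global edit distance between the whole subpattern and every text
    prefix; returns ``(edits, prefix_len)`` pairs within budget."""
    seq = sp.sequence
    wild = sp.wildcard_positions
    m = len(seq)
    n = min(len(text), m + k)
    prev = list(range(m + 1))  # g(0, j) = j
    prev2: Optional[list[int]] = None
    out: list[tuple[int, int]] = []
    if m <= k:
        out.append((m, 0))  # consume nothing, delete the whole pattern
    for i in range(1, n + 1):
        c = text[i - 1]
        cw = c in wildcard_chars
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            if cw or (j - 1) in wild or seq[j - 1] == c:
                best = prev[j - 1]
            else:
                best = prev[j - 1] + 1
            v = prev[j] + 1
            if v < best:
                best = v
            v = cur[j - 1] + 1
            if v < best:
                best = v
            if (
                transpositions and i > 1 and j > 1 and prev2 is not None
                and _cross_match(seq, wild, text, wildcard_chars, i, j)
            ):
                v = prev2[j - 2] + 1
                if v < best:
                    best = v
            cur[j] = best
        if cur[m] <= k:
            out.append((cur[m], i))
        prev2, prev = prev, cur
    full = len(text)
    if overlap_end and n == full and full >= min_overlap:
        # Pattern may overhang the end of the line: pattern characters past
        # row j are free.  `prev` holds g(full, j) because n == full.
        best = None
        for j in range(m, -1, -1):
            if prev[j] <= k and (best is None or prev[j] < best):
                best = prev[j]
        if best is not None and (best, full) not in out:
            out.append((best, full))
    return out
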