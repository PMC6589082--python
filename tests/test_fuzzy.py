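"""Fuzzy search engines against brute-force oracles."""

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzysieve import (
    FuzzyPattern,
    auto_ngram_size,
    best_subpattern_match,
    make_subpattern,
    max_ngram_size,
    ngram_filter,
    search_damerau,
    search_hamming_bitap,
    search_levenshtein,
)
from fuzzysieve.fuzzy import bitap_word_count, build_bitap_masks
from fuzzysieve.patterns import ValueExpr

from oracles import (
    all_strings,
    hamming_matches,
    lev_distance,
    osa_distance,
    semi_global_matches,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=10)
dna_pattern = st.text(alphabet="ACGT", min_size=1, max_size=6)


def _ends(matches):
    return {(m.end, m.edits) for m in matches}


def _check_starts(matches, P, T, dist):
    for m in matches:
        assert 0 <= m.start <= m.end <= len(T)
        assert m.length == m.end - m.start
        assert dist(P, T[m.start:m.end]) == m.edits
        # longest span: no smaller start achieves the same edit count
        assert all(dist(P, T[s:m.end]) > m.edits for s in range(m.start))


# ---------------------------------------------------------------------------
# worked examples


def test_exact_self_match():
    (m,) = search_levenshtein(make_subpattern("ACGT"), "ACGT", 0)
    assert (m.start, m.end, m.edits) == (0, 4, 0)


def test_empty_text_costs_pattern_length():
    (m,) = search_levenshtein(make_subpattern("AC"), "", 2)
    assert (m.start, m.end, m.edits, m.length) == (0, 0, 2, 0)


def test_transposition_costs_one():
    matches = search_damerau(make_subpattern("ACGT"), "ACTG", 1)
    assert (4, 1) in _ends(matches)
    assert search_damerau(make_subpattern("ACGT"), "ACGT", 0)[0].edits == 0


def test_exact_window_hamming():
    (m,) = search_hamming_bitap(make_subpattern("ACGT"), "AACGTT", 0)
    assert (m.start, m.end, m.edits) == (1, 5, 0)


def test_bitap_multiword_mask_count():
    P = make_subpattern("A" * 100)
    masks, default, full = build_bitap_masks(P, word_width=63)
    assert bitap_word_count(100, 63) == 2
    assert len(full) == 2 and len(masks["A"]) == 2


def test_wildcards_match_free():
    P = make_subpattern("ACNT")  # N in the pattern
    assert any(m.edits == 0 for m in search_levenshtein(P, "ACGT", 0))
    P = make_subpattern("ACGT")  # N in the text
    assert any(m.edits == 0 for m in search_levenshtein(P, "ACNT", 0))
    assert any(m.edits == 0 for m in search_hamming_bitap(P, "ANGT", 0))


def test_overlap_end_allows_overhang():
    # only the first 2 of 4 pattern chars fit before the text ends
    P = make_subpattern("ACGT")
    matches = search_levenshtein(P, "TTAC", 0, overlap_end=True)
    assert any(m.end == 4 and m.start == 2 and m.edits == 0 for m in matches)
    # without the flag, ending at |T| costs the unmatched suffix
    assert not any(
        m.edits == 0 for m in search_levenshtein(P, "TTAC", 0))


def test_overlap_start_allows_overhang():
    P = make_subpattern("ACGT")
    matches = search_levenshtein(P, "GTAA", 0, overlap_start=True)
    assert any(m.start == 0 and m.end == 2 and m.edits == 0 for m in matches)


def test_min_overlap_suppresses_tiny_overhangs():
    P = make_subpattern("ACGT")
    matches = search_levenshtein(P, "TTTA", 0, overlap_end=True, min_overlap=3)
    assert not any(m.edits == 0 for m in matches)


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence (small binary alphabet)

EXHAUSTIVE_CASES = [
    (P, T, k)
    for P in all_strings("AC", 3, min_len=1)
    for T in all_strings("AC", 5)
    for k in (0, 1, 2)
]


def test_levenshtein_matches_brute_force_exhaustively():
    for P, T, k in EXHAUSTIVE_CASES:
        sp = make_subpattern(P)
        got = search_levenshtein(sp, T, k)
        assert _ends(got) == semi_global_matches(P, T, k, lev_distance), (P, T, k)
        _check_starts(got, P, T, lev_distance)


def test_damerau_matches_brute_force_exhaustively():
    for P, T, k in EXHAUSTIVE_CASES:
        sp = make_subpattern(P)
        got = search_damerau(sp, T, k)
        assert _ends(got) == semi_global_matches(P, T, k, osa_distance), (P, T, k)
        _check_starts(got, P, T, osa_distance)


def test_hamming_matches_naive_window_counter_exhaustively():
    for P, T, k in EXHAUSTIVE_CASES:
        got = search_hamming_bitap(make_subpattern(P), T, k)
        assert _ends(got) == hamming_matches(P, T, k), (P, T, k)
        assert all(m.length == len(P) for m in got)


def test_cutoff_is_transparent_exhaustively():
    for P, T, k in EXHAUSTIVE_CASES:
        sp = make_subpattern(P)
        for search in (search_levenshtein, search_damerau):
            assert search(sp, T, k, use_cutoff=True) == \
                search(sp, T, k, use_cutoff=False), (P, T, k, search)


# ---------------------------------------------------------------------------
# randomized sweeps over the full domain


@settings(max_examples=300, derandomize=True, deadline=None)
@given(P=dna_pattern, T=dna, k=st.integers(0, 2))
def test_levenshtein_random_vs_oracle_and_edlib(P, T, k):
    sp = make_subpattern(P)
    got = search_levenshtein(sp, T, k)
    assert _ends(got) == semi_global_matches(P, T, k, lev_distance)
    _check_starts(got, P, T, lev_distance)
    # independent cross-check: edlib's infix (HW) distance equals our best
    best = min((m.edits for m in got), default=None)
    ed = edlib.align(P, T, mode="HW", task="distance")["editDistance"]
    assert best == (ed if ed <= k else None)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(P=dna_pattern, T=dna, k=st.integers(0, 2))
def test_damerau_random_vs_oracle(P, T, k):
    sp = make_subpattern(P)
    got = search_damerau(sp, T, k)
    assert _ends(got) == semi_global_matches(P, T, k, osa_distance)
    _check_starts(got, P, T, osa_distance)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(P=st.text(alphabet="ACGT", min_size=1, max_size=130), T=dna,
       k=st.integers(0, 3), w=st.sampled_from([7, 63]))
def test_hamming_multiword_random_vs_oracle(P, T, k, w):
    got = search_hamming_bitap(make_subpattern(P), T, k, word_width=w)
    assert _ends(got) == hamming_matches(P, T, k)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(P=dna_pattern, T=dna, k=st.integers(0, 1))
def test_match_set_grows_with_k(P, T, k):
    sp = make_subpattern(P)
    for search in (search_levenshtein, search_damerau, search_hamming_bitap):
        small = {m.end for m in search(sp, T, k)}
        large = {m.end for m in search(sp, T, k + 1)}
        assert small <= large


@settings(max_examples=200, derandomize=True, deadline=None)
@given(P=dna_pattern, T=dna, k=st.integers(0, 2))
def test_hamming_match_implies_levenshtein_match(P, T, k):
    sp = make_subpattern(P)
    lev = {m.end: m.edits for m in search_levenshtein(sp, T, k)}
    for m in search_hamming_bitap(sp, T, k):
        assert m.end in lev and lev[m.end] <= m.edits


# ---------------------------------------------------------------------------
# n-gram elimination


@pytest.mark.parametrize("L,k,expected", [
    (30, 1, 15),
    (8, 1, 4),
    (1, 0, 1),
    (7, 0, 7),
    (9, 1, 4),
    (2, 3, 0),  # filter unusable
])
def test_max_ngram_size(L, k, expected):
    assert max_ngram_size(L, k) == expected


def test_max_ngram_is_tight():
    # n_max satisfies the inequality, n_max + 1 does not
    for L in range(1, 40):
        for k in range(0, 4):
            n = max_ngram_size(L, k)
            if n:
                assert n < (L - k) / (k + 1) + 1
            assert not (n + 1) < (L - k) / (k + 1) + 1


def test_verbatim_subpattern_survives():
    subs = [make_subpattern("ACGTAC")]
    for n in range(1, 7):
        assert ngram_filter(subs, "TTACGTACTT", 0, n) == {0}


def test_filter_can_eliminate_long_subpatterns_only():
    # |P|=8, k=1, n=4: 8 > (1+1)(4-1)+1 = 7, so elimination is allowed
    absent = make_subpattern("ACGTACGT")
    short = make_subpattern("ACGTACG")  # length 7 fails the inequality
    survivors = ngram_filter([absent, short], "TTTTTTTTTT", 1, 4)
    assert survivors == {1}


def test_filter_skipped_for_wildcards():
    wild_sub = make_subpattern("ACGTNCGT")
    assert ngram_filter([wild_sub], "TTTTTTTT", 1, 4) == {0}
    plain = make_subpattern("ACGTACGT")
    assert ngram_filter([plain], "TTTTNTTT", 1, 4) == {0}  # wildcard in text


def test_filter_soundness_sweep():
    """Whenever |P| > (k+1)(n-1)+k and P occurs within k edits, P survives."""
    for P in all_strings("AC", 5, min_len=3):
        sp = make_subpattern(P)
        for T in all_strings("AC", 6):
            for k in (0, 1):
                if not search_levenshtein(sp, T, k):
                    continue
                for n in range(1, len(P) + 1):
                    if len(P) > (k + 1) * (n - 1) + k:
                        assert 0 in ngram_filter([sp], T, k, n), (P, T, k, n)


def test_auto_size_is_minimum_over_subpatterns():
    subs = [make_subpattern("A" * 30), make_subpattern("ACGTACGT")]
    assert auto_ngram_size(subs, 1) == 4
    assert auto_ngram_size([make_subpattern("ACNT")], 1) == 0  # wildcard


# ---------------------------------------------------------------------------
# combined candidate streams


def _fuzzy(seqs, k, **kw):
    pat = FuzzyPattern(source=ValueExpr.literal("x"), max_edits=k, **kw)
    return pat.with_subpatterns([make_subpattern(s) for s in seqs])


def test_exact_subpattern_ranks_first_at_its_end():
    pat = _fuzzy(["ACGT", "GGGG"], 1)
    cands = best_subpattern_match(pat, "TTACGTTT")
    exact = [c for c in cands if c.edits == 0]
    assert exact and exact[0].subpattern_idx == 0


def test_lowest_edit_candidate_preferred_at_same_end():
    # both subpatterns match ending at 4; the 0-edit one must come first
    pat = _fuzzy(["ACGT", "ACGA"], 1)
    cands = best_subpattern_match(pat, "ACGT")
    at4 = [c for c in cands if c.end == 4]
    assert at4[0].edits == 0 and at4[0].subpattern_idx == 0


def test_candidate_order_matches_unfiltered_brute_force():
    subs = ["ACA", "CAC", "AAC"]
    for T in all_strings("AC", 6):
        pat = _fuzzy(subs, 1)
        got = best_subpattern_match(pat, T)
        expected = []
        for idx, s in enumerate(subs):
            for end, edits in semi_global_matches(s, T, 1, lev_distance):
                expected.append((end, edits, idx))
        expected.sort()
        assert [(c.end, c.edits, c.subpattern_idx) for c in got] == expected

        filtered = best_subpattern_match(pat, T, use_filter=False)
        assert filtered == got  # filter never changes the candidate stream


def test_from_index_restricts_and_offsets():
    pat = _fuzzy(["ACGT"], 0)
    cands = best_subpattern_match(pat, "ACGTACGT", from_index=2)
    assert all(c.start >= 2 for c in cands)
    assert any((c.start, c.end) == (4, 8) and c.edits == 0 for c in cands)
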