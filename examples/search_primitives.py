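"""The matching primitives, used directly as a library.

Shows the three fuzzy searchers (one candidate per end position), the
interval-chunk tiling DP, and the n-gram pre-elimination filter.
"""

from fuzzysieve import (
    IntervalPattern,
    make_subpattern,
    match_interval_chunk,
    max_ngram_size,
    ngram_filter,
    parse_char_class,
    search_damerau,
    search_hamming_bitap,
    search_levenshtein,
)

P = make_subpattern("ACGT")

print("Levenshtein, k=1, pattern ACGT in TTACGTTT:")
for m in search_levenshtein(P, "TTACGTTT", 1):
    print(f"  [{m.start}:{m.end})  edits={m.edits}")

print("restricted Damerau (transpositions), k=1, in TTACTGTT:")
for m in search_damerau(P, "TTACTGTT", 1):
    print(f"  [{m.start}:{m.end})  edits={m.edits}")

print("Hamming via Bitap, k=1, in AAGTAA:")
for m in search_hamming_bitap(P, "AAGTAA", 1):
    print(f"  [{m.start}:{m.end})  mismatches={m.edits}")

# interval-length wildcard chunk: [A-Z] x [0,3] then [0-9] x [1,2]
pats = [
    IntervalPattern(0, 3, parse_char_class("A-Z")),
    IntervalPattern(1, 2, parse_char_class("0-9")),
]
for text in ("ABC12", "12", "ABCD1", "ABC"):
    ok = match_interval_chunk(pats, text, 0, len(text))
    print(f"[A-Z]{{0,3}}[0-9]{{1,2}} tiles {text!r}: {ok}")

# n-gram elimination: a 30-mer at one edit admits 15-grams; an absent
# subpattern longer than (k+1)(n-1)+k is eliminated without any DP
print("max n-gram size for |P|=30, k=1:", max_ngram_size(30, 1))
subs = [make_subpattern("ACGTACGT"), make_subpattern("GGGGGGGG")]
survivors = ngram_filter(subs, "TTACGTACGTTT", 1, 4)
print("surviving subpattern indices in TTACGTACGTTT:", sorted(survivors))

# Each searcher reports, per end position, the minimal edit count and the
# longest text span achieving it; the interval DP answers tiling queries in
# O(patterns x length) after one incremental table fill.
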