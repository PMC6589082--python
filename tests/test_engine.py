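"""Greedy chunk matching, variable binding, trimming, record matching."""

import numpy as np
import pytest

from fuzzysieve import (
    FixedWildcardPattern,
    FuzzyMatch,
    FuzzyPattern,
    IntervalPattern,
    LineMatcher,
    MatchEngine,
    VariableError,
    VariableStore,
    apply_trim,
    bind_variables,
    load_template_set,
    match_line,
    partition_chunks,
)
from fuzzysieve.engine import LineMatchResult
from fuzzysieve.patterns import ValueExpr


def fuzzy(seqs, k=0, **kw):
    pat = FuzzyPattern(source=ValueExpr.literal(seqs[0]), max_edits=k, **kw)
    from fuzzysieve import make_subpattern
    return pat.with_subpatterns([make_subpattern(s) for s in seqs])


I = IntervalPattern()
F = fuzzy(["ACGT"])
R = FixedWildcardPattern(length=2)


class TestPartition:
    @pytest.mark.parametrize("patterns,shape", [
        ([I, F, I], [("interval", 1), ("fixed", 1), ("interval", 1)]),
        ([F], [("interval", 0), ("fixed", 1)]),
        ([I, F, R, I, F], [("interval", 1), ("fixed", 2), ("interval", 1),
                           ("fixed", 1)]),
        ([I, I, F, F], [("interval", 2), ("fixed", 2)]),
        ([I], [("interval", 1)]),
    ])
    def test_shapes(self, patterns, shape):
        part = partition_chunks(patterns)
        assert [(kind, len(items)) for kind, items in part.chunks] == shape

    def test_alternation_and_indices(self):
        part = partition_chunks([F, I, R])
        kinds = [kind for kind, _ in part.chunks]
        assert kinds == ["interval", "fixed", "interval", "fixed"]
        all_indices = [idx for _, items in part.chunks for idx, _ in items]
        assert sorted(all_indices) == [0, 1, 2]


class TestMatchLine:
    def test_universal_interval_matches_anything(self):
        for T in ["", "anything at all", "ACGT"]:
            assert match_line([I], T).matched

    def test_barcode_then_suffix(self):
        res = match_line([I, fuzzy(["ACGTACGT"], 1, required=True), I],
                         "ACGTACGTTTTT")
        assert res.matched
        assert res.pattern_spans[1] is not None
        assert res.pattern_spans[1][0] == 0

    def test_required_pattern_beyond_edit_radius_fails(self):
        # 'GGGGGGGG' needs >1 edit anywhere in the text (brute-force checked
        # in the fuzzy oracle suite)
        res = match_line([I, fuzzy(["GGGGGGGG"], 1, required=True), I],
                         "ACACACACACAC")
        assert not res.matched

    def test_optional_chunk_skipped_and_intervals_merged(self):
        # [i max 2][f optional][i max 2] on text needing 4 interval chars
        pats = [IntervalPattern(0, 2), fuzzy(["TTTT"]), IntervalPattern(0, 2)]
        res = match_line(pats, "ACGA")
        assert res.matched
        assert res.pattern_spans[1] is None  # fuzzy never matched

    def test_anchored_line_end(self):
        # no trailing interval: the fuzzy match must end at |T|
        pats = [I, fuzzy(["ACGT"], 0, required=True)]
        assert match_line(pats, "TTTTACGT").matched
        assert not match_line(pats, "TTTTACGTTT").matched

    def test_greedy_not_optimal(self):
        """Documented adversarial case: the greedy matcher commits to the
        first 'AB' and cannot place the required 'CD' adjacent to it, even
        though the segmentation using the second 'AB' exists."""
        pats = [
            fuzzy(["AB"], required=True),
            IntervalPattern(0, 0),
            fuzzy(["CD"], required=True),
            I,
        ]
        assert match_line(pats, "ABCDXX").matched
        assert not match_line(pats, "ABABCD").matched

    def test_min_interval_constrains_gap(self):
        pats = [IntervalPattern(2, None), fuzzy(["ACGT"], 0, required=True), I]
        assert match_line(pats, "TTACGT").matched
        assert not match_line(pats, "ACGTTT").matched  # barcode at 0: gap too small

    def test_binds_variables_on_success_only(self):
        vars = VariableStore()
        res = match_line([I, fuzzy(["ACGT"], 0, required=True, name="b"), I],
                         "TTACGTTT", vars)
        assert res.matched
        assert vars.lookup("b.length") == 4
        assert vars.lookup("b.edits") == 0
        vars2 = VariableStore()
        res = match_line([I, fuzzy(["GGGG"], 0, required=True, name="b")],
                         "TTTT", vars2)
        assert not res.matched
        assert "b" not in vars2.names()

    def test_same_line_forward_reference(self):
        # {f name=b ...}{r length=%b.length%} consumes as many chars again
        pats = [
            fuzzy(["ACG"], 0, required=True, name="b"),
            FixedWildcardPattern(length=ValueExpr.variable("b.length")),
        ]
        assert match_line(pats, "ACGXYZ").matched
        assert not match_line(pats, "ACGXY").matched


class TestCacheTransparency:
    def test_results_identical_with_and_without_caches(self):
        rng = np.random.default_rng(7)
        pats = [
            I,
            fuzzy(["ACGTAC", "GGATCC"], 1, required=True, name="b"),
            FixedWildcardPattern(length=2),
            I,
        ]
        texts = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            for _ in range(40)
        ]
        configs = [
            dict(use_cache=True, use_interval_cache=True),
            dict(use_cache=False, use_interval_cache=True),
            dict(use_cache=True, use_interval_cache=False),
            dict(use_cache=False, use_interval_cache=False),
        ]
        matchers = [LineMatcher(pats, **cfg) for cfg in configs]
        for T in texts:
            results = [m.match(T, VariableStore()) for m in matchers]
            assert all(r == results[0] for r in results[1:])


FASTQ_TEMPLATE = """\
{i}
1 {f required, trim, name = "b", edits = 1, pattern = f"b.txt"}{i}
{i}
2 {r trim, length = %b.length%}{i}
"""


@pytest.fixture
def fastq_engine(write):
    write("b.txt", "ACGTACGT\tBC01\nTTGGCCAA\tBC02\n")
    path = write("template.txt", FASTQ_TEMPLATE)
    return MatchEngine(load_template_set([path]))


class TestMatchRecord:
    def test_trims_sequence_and_quality_equally(self, fastq_engine):
        seq = "ACGTACGT" + "T" * 12
        rec = [["@r1", seq, "+", "J" * len(seq)]]
        res = fastq_engine.match_record(rec)
        assert res.matched
        out_seq, out_qual = res.output_lines[0][1], res.output_lines[0][3]
        assert len(out_seq) == len(out_qual)
        assert res.variables.lookup("b.pattern_name") == "BC01"

    def test_one_edit_barcode_still_matched(self, fastq_engine):
        seq = "ACGAACGT" + "T" * 12  # one substitution in BC01
        res = fastq_engine.match_record([["@r", seq, "+", "I" * len(seq)]])
        assert res.matched
        assert res.variables.lookup("b.edits") == 1
        assert len(res.output_lines[0][1]) == len(res.output_lines[0][3])

    def test_unmatched_record_unchanged(self, fastq_engine):
        lines = ["@r", "CCCCCCCCCCCCCCC", "+", "IIIIIIIIIIIIIII"]
        res = fastq_engine.match_record([lines])
        assert not res.matched
        assert res.output_lines == (tuple(lines),)

    def test_line_count_mismatch_rejected(self, fastq_engine):
        from fuzzysieve import InputError
        with pytest.raises(InputError):
            fastq_engine.match_record([["@r", "ACGT", "+"]])


class TestPairedEnd:
    @pytest.fixture
    def paired_engine(self, write):
        write("f.txt", "AAAACCCC\tF1\nGGGGTTTT\tF2\n")
        write("r.txt", "TTTTGGGG\tR1\nCCCCAAAA\tR2\n")
        fwd = write("fwd.txt", """\
{i}
1 {f required, trim, name = "f", edits = 1, pattern = f"f.txt"}{i}
{i}
2 {r trim, length = %f.length%}{i}
""")
        rev = write("rev.txt", """\
{i}
3 {f required, trim, name = "r", edits = 1, pattern = f"r.txt"[%f.pattern_idx%]}{i}
{i}
4 {r trim, length = %r.length%}{i}
""")
        return MatchEngine(load_template_set([fwd, rev]))

    @staticmethod
    def _record(fwd_seq, rev_seq):
        return [
            ["@r/1", fwd_seq, "+", "I" * len(fwd_seq)],
            ["@r/2", rev_seq, "+", "I" * len(rev_seq)],
        ]

    def test_concordant_pair_matches(self, paired_engine):
        res = paired_engine.match_record(
            self._record("GGGGTTTT" + "A" * 10, "CCCCAAAA" + "G" * 10))
        assert res.matched
        assert res.variables.lookup("f.pattern_name") == "F2"
        assert res.variables.lookup("r.pattern_name") == "R2"

    def test_discordant_pair_fails(self, paired_engine):
        # forward barcode F2 selects R2 for the reverse read; R1 present
        res = paired_engine.match_record(
            self._record("GGGGTTTT" + "A" * 10, "TTTTGGGG" + "G" * 10))
        assert not res.matched
        # reverse lines untouched
        assert res.output_lines[1][1] == "TTTTGGGG" + "G" * 10


class TestBindAndTrim:
    def test_bind_fuzzy_match_statistics(self):
        vars = VariableStore()
        bind_variables("b", FuzzyMatch(3, 0, 8, 1), vars, pattern_name="BC04")
        assert vars.get("b") == {
            "length": 8, "pattern_idx": 3, "pattern_name": "BC04", "edits": 1,
        }

    def test_bind_span_statistics(self):
        vars = VariableStore()
        bind_variables("x", (2, 7), vars)
        assert vars.get("x") == {"length": 5, "edits": 0}

    def test_rebinding_rejected(self):
        vars = VariableStore()
        bind_variables("b", (0, 4), vars)
        with pytest.raises(VariableError):
            bind_variables("b", (0, 4), vars)

    def test_trim_identity_without_spans(self):
        res = LineMatchResult(True, (), ())
        assert apply_trim("ACGT", res) == "ACGT"

    def test_trim_length_arithmetic(self):
        line = "B" * 8 + "X" * 100
        res = LineMatchResult(True, (), ((0, 8),))
        assert len(apply_trim(line, res)) == 100
        res = LineMatchResult(True, (), ((0, 2), (4, 6)))
        assert apply_trim("ABCDEFGH", res) == "CDGH"
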