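"""Greedy template-line matching.

A template line's patterns are partitioned into maximal runs ("chunks") of
interval-length patterns and of fixed-length patterns (fuzzy and fixed-length
wildcard patterns), alternating, with empty interval chunks inserted where
needed so the sequence starts with an interval chunk.

Matching walks the chunk pairs left to right and never backtracks across an
accepted pair.  For each (interval chunk, fixed chunk) pair:

* starting patterns ``s`` are drawn from the fixed chunk's leading
  non-required prefix plus its first required pattern;
* each candidate location of ``s`` (ascending end position, then edit count,
  then subpattern index) anchors a greedy left-to-right match of the chunk's
  remaining patterns, fuzzy patterns taking their lowest-edit anchored
  candidate;
* the candidate is accepted iff the interval chunk tiles the text between the
  running cursor and the candidate start — and, for the final pair, the
  trailing interval chunk tiles the remainder of the line, since nothing
  after it could absorb leftover text.

A fixed chunk whose patterns are all optional and never match is skipped and
its flanking interval chunks merge.  The greedy strategy is deliberate: it
can refuse lines that an exhaustive segmentation search would accept, in
exchange for early termination when a required pattern is absent.

Named patterns bind their match statistics only when the whole line matches;
record-level matching evaluates lines in processing order, sharing one
variable store, and applies trimming only when every line matched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence, Union

from .dsl import ListFileCache, resolve_value
from .errors import InputError, MatchError, TemplateError
from .fuzzy import FuzzyMatch, anchored_matches, iter_pattern_candidates
from .patterns import (
    DEFAULT_WILDCARDS,
    FuzzyPattern,
    IntervalPattern,
    Pattern,
    TemplateSet,
    make_subpattern,
)
from .variables import VariableStore
from .wildcards import IntervalDPState, match_fixed, resolve_length

Span = tuple[int, int]
_Item = tuple[int, Pattern]  # (position in the line's pattern list, pattern)


@dataclass(frozen=True)
class ChunkPartition:
    """Alternating interval / fixed chunks of one template line."""

    pairs: tuple[tuple[tuple[_Item, ...], tuple[_Item, ...]], ...]
    trailing: tuple[_Item, ...]

    @property
    def chunks(self) -> list[tuple[str, tuple[_Item, ...]]]:
        out: list[tuple[str, tuple[_Item, ...]]] = []
        for ichunk, fchunk in self.pairs:
            out.append(("interval", ichunk))
            out.append(("fixed", fchunk))
        if self.trailing:
            out.append(("interval", self.trailing))
        return out


def partition_chunks(patterns: Sequence[Pattern]) -> ChunkPartition:
    """Split a pattern list into alternating interval and fixed chunks.

    Maximal runs keep their kind; an empty interval chunk anchors a fixed
    chunk at the line start.  A trailing interval chunk is kept only when the
    line actually ends with interval patterns.
    """
    if not patterns:
        raise MatchError("cannot partition an empty pattern list")
    runs: list[tuple[str, list[_Item]]] = []
    for idx, pat in enumerate(patterns):
        kind = "interval" if isinstance(pat, IntervalPattern) else "fixed"
        if runs and runs[-1][0] == kind:
            runs[-1][1].append((idx, pat))
        else:
            runs.append((kind, [(idx, pat)]))
    pairs: list[tuple[tuple[_Item, ...], tuple[_Item, ...]]] = []
    trailing: tuple[_Item, ...] = ()
    pending_interval: tuple[_Item, ...] = ()
    for kind, items in runs:
        if kind == "interval":
            pending_interval = tuple(items)
        else:
            pairs.append((pending_interval, tuple(items)))
            pending_interval = ()
    if runs[-1][0] == "interval":
        trailing = pending_interval
    return ChunkPartition(pairs=tuple(pairs), trailing=trailing)


@dataclass
class LineMatchResult:
    """Outcome of matching one line: per-pattern spans (``None`` for skipped
    optional patterns and non-sole interval-chunk members) and the merged
    spans to trim."""

    matched: bool
    pattern_spans: tuple[Optional[Span], ...]
    trim_spans: tuple[Span, ...]


@dataclass
class RecordResult:
    """Outcome of matching one record (a line group across all input files).

    Unmatched records keep their lines byte-identical; matched records have
    trim spans removed.
    """

    matched: bool
    output_lines: tuple[tuple[str, ...], ...]
    variables: VariableStore


def bind_variables(
    name: str,
    match: Union[FuzzyMatch, Span],
    vars: VariableStore,
    pattern_name: Optional[str] = None,
) -> None:
    """Bind ``name.length/pattern_idx/pattern_name/edits`` for a fuzzy match,
    or ``name.length/edits`` for a plain span."""
    if isinstance(match, FuzzyMatch):
        vars.bind(name, {
            "length": match.length,
            "pattern_idx": match.subpattern_idx,
            "pattern_name": pattern_name if pattern_name is not None else "",
            "edits": match.edits,
        })
    else:
        start, end = match
        vars.bind(name, {"length": end - start, "edits": 0})


def apply_trim(line: str, result: LineMatchResult) -> str:
    """Remove the trim spans from a matched line, keeping the rest in order."""
    if not result.matched:
        raise MatchError("apply_trim requires a matched line")
    if not result.trim_spans:
        return line
    spans = sorted(result.trim_spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise MatchError(f"overlapping trim spans ({s1},{e1}) and ({s2},{e2})")
    out: list[str] = []
    pos = 0
    for s, e in spans:
        out.append(line[pos:s])
        pos = e
    out.append(line[pos:])
    return "".join(out)


class LineMatcher:
    """Matches one template line's patterns against text lines.

    Holds the per-run configuration (wildcard characters, cache and cutoff
    toggles) and the list-file cache; per-line state is local to each
    :meth:`match` call so a matcher is reusable across records.
    """

    def __init__(
        self,
        patterns: Sequence[Pattern],
        lists: Optional[ListFileCache] = None,
        *,
        wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
        use_cutoff: bool = True,
        use_cache: bool = True,
        use_interval_cache: bool = True,
        use_filter: bool = True,
        ngram_override: Optional[int] = None,
    ):
        self.patterns = tuple(patterns)
        self.partition = partition_chunks(self.patterns)
        self.lists = lists if lists is not None else ListFileCache()
        self.wildcard_chars = wildcard_chars
        self.use_cutoff = use_cutoff
        self.use_cache = use_cache
        self.use_interval_cache = use_interval_cache
        self.use_filter = use_filter
        self.ngram_override = ngram_override
        # file-backed fuzzy patterns with no selection operator resolve
        # identically for every record: materialize them once
        self._static: dict[int, FuzzyPattern] = {}

    # -- pattern materialization ------------------------------------------

    def _materialize(self, idx: int, pat: FuzzyPattern,
                     vars: VariableStore) -> FuzzyPattern:
        if pat.subpatterns is not None:
            return pat
        static = pat.source.kind in ("literal", "file_ref")
        if static and idx in self._static:
            return self._static[idx]
        value = resolve_value(pat.source, vars, self.lists)
        if isinstance(value, str):
            subs = [make_subpattern(value, None, self.wildcard_chars)]
        elif isinstance(value, list):
            subs = value
        else:
            raise TemplateError(
                f"fuzzy pattern source resolved to {value!r}, expected a "
                "sequence or subpattern list"
            )
        if self.ngram_override is not None and pat.ngram == "auto":
            pat = replace(pat, ngram=self.ngram_override)
        mat = pat.with_subpatterns(subs)
        if static:
            self._static[idx] = mat
        return mat

    # -- candidate generation ---------------------------------------------

    def _start_candidates(
        self, pat: Pattern, fp: Optional[FuzzyPattern], T: str, cursor: int,
        vars: VariableStore,
    ) -> Iterator[FuzzyMatch]:
        if isinstance(pat, FuzzyPattern):
            assert fp is not None
            yield from iter_pattern_candidates(
                fp, T, cursor, use_cutoff=self.use_cutoff,
                use_filter=self.use_filter,
                wildcard_chars=self.wildcard_chars,
            )
        else:
            L = resolve_length(pat, vars)
            for pos in range(cursor, len(T) - L + 1):
                if match_fixed(pat, T, pos, vars):
                    yield FuzzyMatch(0, pos, pos + L, 0)

    def _match_tail(
        self, items: Sequence[_Item], T: str, pos: int, vars: VariableStore,
        cache: dict,
    ):
        """Greedily match the fixed-chunk patterns after the starting pattern,
        consecutively from ``pos``.  Returns ``(end, matches, bindings)`` or
        ``None``; ``matches`` is a list of ``(idx, span, stats, trim)``."""
        attempt = vars.child()
        matched: list[tuple[int, Span, Optional[dict], bool]] = []
        for idx, pat in items:
            if isinstance(pat, FuzzyPattern):
                fp = self._materialize(idx, pat, attempt)
                cacheable = self.use_cache and pat.source.kind in ("literal", "file_ref")
                key = (idx, pos)
                if cacheable and key in cache:
                    cands = cache[key]
                else:
                    cands = anchored_matches(
                        fp, T, pos, wildcard_chars=self.wildcard_chars)
                    if cacheable:
                        cache[key] = cands
                if cands:
                    edits, end, sidx = cands[0]
                    stats = None
                    if fp.name:
                        stats = {
                            "length": end - pos,
                            "pattern_idx": sidx,
                            "pattern_name": fp.subpatterns[sidx].display_name,
                            "edits": edits,
                        }
                        attempt.bind(fp.name, stats)
                    matched.append((idx, (pos, end), stats, fp.trim))
                    pos = end
                elif pat.required:
                    return None
            else:
                L = resolve_length(pat, attempt)
                if match_fixed(pat, T, pos, attempt):
                    stats = None
                    if pat.name:
                        stats = {"length": L, "edits": 0}
                        attempt.bind(pat.name, stats)
                    matched.append((idx, (pos, pos + L), stats, pat.trim))
                    pos += L
                elif pat.required:
                    return None
        return pos, matched, attempt

    # -- line matching -----------------------------------------------------

    def match(self, T: str, vars: Optional[VariableStore] = None) -> LineMatchResult:
        """Match the line's patterns against ``T``; on success, commit the
        bindings of named matched patterns into ``vars``."""
        if vars is None:
            vars = VariableStore()
        line_vars = vars.child()
        n = len(T)
        spans: list[Optional[Span]] = [None] * len(self.patterns)
        trims: list[Span] = []
        cursor = 0
        pending: tuple[_Item, ...] = ()
        tail_cache: dict = {}
        pairs = self.partition.pairs

        def record_interval(items: Sequence[_Item], start: int, end: int) -> None:
            if len(items) == 1:
                idx, pat = items[0]
                spans[idx] = (start, end)
                if pat.name:
                    bind_variables(pat.name, (start, end), line_vars)
            if end > start and any(p.trim for _, p in items):
                trims.append((start, end))

        for pair_i, (ichunk, fchunk) in enumerate(pairs):
            is_last = pair_i == len(pairs) - 1
            interval_items = pending + ichunk
            ipats = [p for _, p in interval_items]
            istate = IntervalDPState(ipats, T, cursor)

            def interval_ok(end: int) -> bool:
                if self.use_interval_cache:
                    return istate.matches(end)
                return IntervalDPState(ipats, T, cursor).matches(end)

            trailing_pats = [p for _, p in self.partition.trailing]
            accepted = None
            for s_pos, (s_idx, s_pat) in enumerate(fchunk):
                fp = (
                    self._materialize(s_idx, s_pat, line_vars)
                    if isinstance(s_pat, FuzzyPattern) else None
                )
                for cand in self._start_candidates(s_pat, fp, T, cursor, line_vars):
                    # stage the starting pattern's binding so tail patterns
                    # on the same line can already reference it
                    staged = line_vars.child()
                    if isinstance(s_pat, FuzzyPattern):
                        if fp.name:
                            bind_variables(
                                fp.name, cand, staged,
                                pattern_name=fp.subpatterns[
                                    cand.subpattern_idx].display_name,
                            )
                    elif s_pat.name:
                        bind_variables(s_pat.name, (cand.start, cand.end), staged)
                    tail = self._match_tail(
                        fchunk[s_pos + 1:], T, cand.end, staged, tail_cache)
                    if tail is None:
                        continue
                    end, tail_matches, attempt = tail
                    if not interval_ok(cand.start):
                        continue
                    if is_last and not IntervalDPState(
                            trailing_pats, T, end).matches(n):
                        continue
                    accepted = (s_idx, s_pat, cand, end, tail_matches,
                                attempt, staged)
                    break
                if accepted is not None:
                    break
                if getattr(s_pat, "required", False):
                    break  # later starting patterns would skip a required one
            if accepted is None:
                if any(getattr(p, "required", False) for _, p in fchunk):
                    return LineMatchResult(False, tuple(spans), ())
                pending = interval_items  # merge flanking interval chunks
                continue
            s_idx, s_pat, cand, end, tail_matches, attempt, staged = accepted
            record_interval(interval_items, cursor, cand.start)
            spans[s_idx] = (cand.start, cand.end)
            if cand.end > cand.start and getattr(s_pat, "trim", False):
                trims.append((cand.start, cand.end))
            for idx, span, stats, trim in tail_matches:
                spans[idx] = span
                if span[1] > span[0] and trim:
                    trims.append(span)
            attempt.commit()  # tail bindings into the staged store
            staged.commit()  # staged bindings into line_vars
            cursor = end
            pending = ()

        final_items = pending + self.partition.trailing
        fpats = [p for _, p in final_items]
        if not IntervalDPState(fpats, T, cursor).matches(n):
            return LineMatchResult(False, tuple(spans), ())
        record_interval(final_items, cursor, n)
        line_vars.commit()
        return LineMatchResult(True, tuple(spans), tuple(trims))


def match_line(
    patterns: Sequence[Pattern],
    T: str,
    vars: Optional[VariableStore] = None,
    lists: Optional[ListFileCache] = None,
    **options,
) -> LineMatchResult:
    """One-shot wrapper around :class:`LineMatcher`."""
    return LineMatcher(patterns, lists, **options).match(T, vars)


class MatchEngine:
    """Record-level matcher for a template set (one template per input file)."""

    def __init__(
        self,
        template_set: TemplateSet,
        *,
        wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
        use_cutoff: bool = True,
        use_cache: bool = True,
        use_interval_cache: bool = True,
        use_filter: bool = True,
        ngram_override: Optional[int] = None,
    ):
        self.template_set = template_set
        self._matchers: dict[tuple[int, int], LineMatcher] = {}
        for slot, spec in enumerate(template_set.specs):
            lists = ListFileCache(spec.base_dir, wildcard_chars)
            for li, line in enumerate(spec.lines):
                self._matchers[(slot, li)] = LineMatcher(
                    line.patterns, lists,
                    wildcard_chars=wildcard_chars,
                    use_cutoff=use_cutoff,
                    use_cache=use_cache,
                    use_interval_cache=use_interval_cache,
                    use_filter=use_filter,
                    ngram_override=ngram_override,
                )
        self._order = template_set.processing_order()

    def match_record(self, lines_per_file: Sequence[Sequence[str]]) -> RecordResult:
        """Match one record; trims apply only when every line matches."""
        specs = self.template_set.specs
        if len(lines_per_file) != len(specs):
            raise InputError(
                f"record has {len(lines_per_file)} files, template set has "
                f"{len(specs)}"
            )
        for slot, spec in enumerate(specs):
            if len(lines_per_file[slot]) != spec.group_size:
                raise InputError(
                    f"file {slot}: record has {len(lines_per_file[slot])} lines, "
                    f"template expects {spec.group_size}"
                )
        vars = VariableStore()
        results: dict[tuple[int, int], LineMatchResult] = {}
        matched = True
        for slot, li in self._order:
            text = lines_per_file[slot][li]
            res = self._matchers[(slot, li)].match(text, vars)
            results[(slot, li)] = res
            if not res.matched:
                matched = False
                break
        if matched:
            output = tuple(
                tuple(
                    apply_trim(lines_per_file[slot][li], results[(slot, li)])
                    for li in range(spec.group_size)
                )
                for slot, spec in enumerate(specs)
            )
        else:
            output = tuple(tuple(lines) for lines in lines_per_file)
        return RecordResult(matched=matched, output_lines=output, variables=vars)
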