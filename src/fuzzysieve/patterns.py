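"""Typed pattern objects built from template files.

Three pattern kinds describe a read schematic:

* :class:`FuzzyPattern` — one of several literal subpatterns (barcodes,
  adapters) matched under an edit-distance metric with up to ``max_edits``
  edits;
* :class:`FixedWildcardPattern` — a run of exactly ``length`` characters from
  an allowed character class;
* :class:`IntervalPattern` — a run of characters from an allowed class whose
  length lies in ``[min_len, max_len]``.

Patterns are arranged on :class:`TemplateLine`\\ s; a :class:`TemplateSpec`
groups the lines matched against each consecutive block of input lines, and a
:class:`TemplateSet` aligns one spec per input file for paired inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

from .errors import TemplateError

#: Characters treated as match-anything wildcards by default (the undetermined
#: base in nucleotide data).
DEFAULT_WILDCARDS = frozenset("N")

METRICS = ("hamming", "levenshtein", "damerau")
OVERLAPS = ("none", "start", "end", "both")


@dataclass(frozen=True)
class CharClass:
    """A set of allowed characters, or the universal class (``allowed=None``).

    ``source_spec`` keeps the literal range string (e.g. ``"a-z0-9"``) so
    templates round-trip through serialization.
    """

    allowed: Optional[frozenset[str]] = None
    source_spec: Optional[str] = None

    def __contains__(self, ch: str) -> bool:
        return self.allowed is None or ch in self.allowed

    @property
    def is_universal(self) -> bool:
        return self.allowed is None

    def __len__(self) -> int:
        if self.allowed is None:
            raise TypeError("universal character class has no size")
        return len(self.allowed)


UNIVERSAL = CharClass()


@dataclass(frozen=True)
class Subpattern:
    """One literal subpattern (a single barcode/adapter sequence).

    ``wildcard_positions`` are indices that match any text character at zero
    cost.  ``name`` defaults to the sequence itself when a list file carries
    no name column.
    """

    sequence: str
    name: Optional[str] = None
    wildcard_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise TemplateError("subpattern sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def display_name(self) -> str:
        return self.name if self.name is not None else self.sequence


def make_subpattern(
    sequence: str,
    name: Optional[str] = None,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
) -> Subpattern:
    """Build a subpattern, deriving wildcard positions from ``wildcard_chars``."""
    pos = frozenset(i for i, ch in enumerate(sequence) if ch in wildcard_chars)
    return Subpattern(sequence=sequence, name=name, wildcard_positions=pos)


@dataclass(frozen=True)
class ValueExpr:
    """A parameter value: literal, ``%var.field%``, ``f"path"`` or
    ``f"path"[selector]``."""

    kind: str  # literal | variable_ref | file_ref | file_ref_selected
    payload: Union[int, str]
    selector: Optional["ValueExpr"] = None

    @classmethod
    def literal(cls, value: Union[int, str]) -> "ValueExpr":
        return cls("literal", value)

    @classmethod
    def variable(cls, ref: str) -> "ValueExpr":
        return cls("variable_ref", ref)

    @classmethod
    def file(cls, path: str, selector: Optional["ValueExpr"] = None) -> "ValueExpr":
        if selector is None:
            return cls("file_ref", path)
        return cls("file_ref_selected", path, selector)


@dataclass(frozen=True)
class FuzzyPattern:
    """Fuzzy pattern: one of ``subpatterns`` matched with up to ``max_edits``
    edits under ``metric``; exactly one subpattern is chosen per match."""

    source: ValueExpr  # literal sequence, file ref, or selected file ref
    max_edits: int = 0
    metric: str = "levenshtein"
    required: bool = False
    trim: bool = False
    name: Optional[str] = None
    overlap: str = "none"  # which text ends allow partial pattern overhang
    min_overlap: int = 1  # minimum in-text characters when overhanging
    ngram: Union[str, int] = "auto"  # "auto" | 0 (disabled) | explicit size
    subpatterns: Optional[tuple[Subpattern, ...]] = None  # materialized lazily

    def __post_init__(self):
        if self.max_edits < 0:
            raise TemplateError("edits must be non-negative")
        if self.metric not in METRICS:
            raise TemplateError(f"unknown metric {self.metric!r}; one of {METRICS}")
        if self.overlap not in OVERLAPS:
            raise TemplateError(f"unknown overlap {self.overlap!r}; one of {OVERLAPS}")
        if self.subpatterns is not None and len(self.subpatterns) == 0:
            raise TemplateError("fuzzy pattern needs at least one subpattern")

    @property
    def overlap_start(self) -> bool:
        return self.overlap in ("start", "both")

    @property
    def overlap_end(self) -> bool:
        return self.overlap in ("end", "both")

    def with_subpatterns(self, subs: Sequence[Subpattern]) -> "FuzzyPattern":
        return replace(self, subpatterns=tuple(subs))


@dataclass(frozen=True)
class FixedWildcardPattern:
    """Fixed-length wildcard: exactly ``length`` characters, all in
    ``char_class``.  ``length`` may be a variable reference resolved at match
    time (e.g. the length of an earlier barcode match)."""

    length: Union[int, ValueExpr]
    char_class: CharClass = UNIVERSAL
    trim: bool = False
    required: bool = False
    name: Optional[str] = None

    def __post_init__(self):
        if isinstance(self.length, int) and self.length < 1:
            raise TemplateError("fixed-length pattern length must be >= 1")


@dataclass(frozen=True)
class IntervalPattern:
    """Interval-length wildcard: a run of ``char_class`` characters whose
    length lies in ``[min_len, max_len]``; ``max_len=None`` is unbounded."""

    min_len: int = 0
    max_len: Optional[int] = None
    char_class: CharClass = UNIVERSAL
    trim: bool = False
    name: Optional[str] = None

    def __post_init__(self):
        if self.min_len < 0:
            raise TemplateError("interval min must be non-negative")
        if self.max_len is not None and self.min_len > self.max_len:
            raise TemplateError(
                f"interval min {self.min_len} exceeds max {self.max_len}"
            )


Pattern = Union[FuzzyPattern, FixedWildcardPattern, IntervalPattern]


@dataclass(frozen=True)
class TemplateLine:
    """One template line: an ordered run of patterns matched against one input
    line.  ``order_index`` controls the processing order across a record so
    variables exist before they are referenced."""

    patterns: tuple[Pattern, ...]
    order_index: Optional[int] = None
    file_slot: int = 0

    def __post_init__(self):
        if not self.patterns:
            raise TemplateError("template line must contain at least one pattern")


@dataclass(frozen=True)
class TemplateSpec:
    """A parsed template for one input file.

    ``group_size`` — the number of lines per record — always equals the number
    of template lines; the template repeats over every consecutive group of
    that many input lines.
    """

    lines: tuple[TemplateLine, ...]
    base_dir: str = "."

    def __post_init__(self):
        if not self.lines:
            raise TemplateError("template is empty")
        seen: set[int] = set()
        for line in self.lines:
            idx = line.order_index
            if idx is not None:
                if idx in seen:
                    raise TemplateError(f"duplicate order index {idx}")
                seen.add(idx)

    @property
    def group_size(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class TemplateSet:
    """One template per input file, with a single record-wide processing
    order: explicitly indexed lines first (ascending index), then unindexed
    lines in (file, source) order."""

    specs: tuple[TemplateSpec, ...]

    def __post_init__(self):
        if not self.specs:
            raise TemplateError("template set is empty")
        seen: set[int] = set()
        for spec in self.specs:
            for line in spec.lines:
                if line.order_index is not None:
                    if line.order_index in seen:
                        raise TemplateError(
                            f"duplicate order index {line.order_index} across templates"
                        )
                    seen.add(line.order_index)

    def processing_order(self) -> list[tuple[int, int]]:
        """Return ``(file_slot, line_index)`` pairs in processing order."""
        indexed: list[tuple[int, int, int]] = []
        unindexed: list[tuple[int, int]] = []
        for slot, spec in enumerate(self.specs):
            for li, line in enumerate(spec.lines):
                if line.order_index is not None:
                    indexed.append((line.order_index, slot, li))
                else:
                    unindexed.append((slot, li))
        indexed.sort()
        return [(slot, li) for _, slot, li in indexed] + unindexed
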