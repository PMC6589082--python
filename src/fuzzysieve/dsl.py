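"""Parser for the template language and list files.

Grammar (one template line per input line):

* an optional leading integer followed by whitespace gives the line's
  processing ``order_index``;
* patterns are brace-delimited tokens ``{<kind> <params>}`` whose first
  character selects the kind: ``f`` fuzzy, ``r`` fixed-length wildcard,
  ``i`` interval-length wildcard;
* parameters are comma-separated ``key = value`` pairs; ``required`` and
  ``trim`` are bare flags;
* values are integers, double-quoted strings, ``%name.field%`` variable
  references, or ``f"path"`` file references with an optional ``[selector]``
  selection operator;
* lines starting with ``#`` are comments and are ignored, as are blank lines.

Example (demultiplex 5' barcodes in a FASTQ file, trimming the quality line
by the same number of characters)::

    {i}
    1 {f required, trim, name = "b", edits = 1, pattern = f"b.txt"}{i}
    {i}
    2 {r trim, length = %b.length%}{i}

List files hold one subpattern per line with an optional TAB-separated name
column.
"""

from __future__ import annotations

import os
import re
import warnings
from typing import Optional, Sequence, Union

from .errors import TemplateError, VariableError
from .patterns import (
    DEFAULT_WILDCARDS,
    UNIVERSAL,
    CharClass,
    FixedWildcardPattern,
    FuzzyPattern,
    IntervalPattern,
    Pattern,
    Subpattern,
    TemplateLine,
    TemplateSet,
    TemplateSpec,
    ValueExpr,
    make_subpattern,
)
from .variables import VariableStore

_TOKEN_RE = re.compile(r"\{([^{}]*)\}")
_ORDER_RE = re.compile(r"^(\d+)\s+")
_INT_RE = re.compile(r"^-?\d+$")
_VAR_RE = re.compile(r"^%([A-Za-z_][\w.]*)%$")
_FILE_RE = re.compile(r'^f"([^"]*)"(?:\[(.*)\])?$')
_STR_RE = re.compile(r'^"([^"]*)"$')

_KEYS = {
    "f": {"required", "trim", "name", "edits", "pattern", "metric", "overlap",
          "min_overlap", "ngram"},
    "r": {"required", "trim", "name", "length", "pattern"},
    "i": {"trim", "name", "min", "max", "pattern"},
}


def parse_char_class(spec: Optional[str]) -> CharClass:
    """Parse a range string like ``"a-z0-9"`` into a :class:`CharClass`.

    An absent spec yields the universal class.  A range ``x-y`` requires
    ``ord(x) <= ord(y)``; a trailing hyphen is an error.
    """
    if spec is None:
        return UNIVERSAL
    allowed: set[str] = set()
    i = 0
    while i < len(spec):
        if i + 1 < len(spec) and spec[i + 1] == "-":
            if i + 2 >= len(spec):
                raise TemplateError(f"dangling hyphen in character class {spec!r}")
            lo, hi = spec[i], spec[i + 2]
            if ord(lo) > ord(hi):
                raise TemplateError(
                    f"descending range {lo}-{hi} in character class {spec!r}"
                )
            allowed.update(chr(c) for c in range(ord(lo), ord(hi) + 1))
            i += 3
        else:
            allowed.add(spec[i])
            i += 1
    if not allowed:
        raise TemplateError("empty character class")
    return CharClass(allowed=frozenset(allowed), source_spec=spec)


def _parse_value(text: str) -> ValueExpr:
    text = text.strip()
    if _INT_RE.match(text):
        return ValueExpr.literal(int(text))
    m = _VAR_RE.match(text)
    if m:
        return ValueExpr.variable(m.group(1))
    m = _FILE_RE.match(text)
    if m:
        path, sel = m.group(1), m.group(2)
        return ValueExpr.file(path, None if sel is None else _parse_value(sel))
    m = _STR_RE.match(text)
    if m:
        return ValueExpr.literal(m.group(1))
    raise TemplateError(f"cannot parse parameter value {text!r}")


def _split_params(body: str) -> list[str]:
    """Split on top-level commas, respecting quotes and brackets."""
    parts, depth, in_str, cur = [], 0, False, []
    for ch in body:
        if ch == '"':
            in_str = not in_str
            cur.append(ch)
        elif in_str:
            cur.append(ch)
        elif ch == "[":
            depth += 1
            cur.append(ch)
        elif ch == "]":
            depth -= 1
            cur.append(ch)
        elif ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if in_str or depth != 0:
        raise TemplateError(f"unbalanced quotes or brackets in {body!r}")
    parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


def _expect_str(expr: ValueExpr, key: str) -> str:
    if expr.kind != "literal" or not isinstance(expr.payload, str):
        raise TemplateError(f"parameter {key!r} must be a quoted string")
    return expr.payload


def _expect_int(expr: ValueExpr, key: str) -> int:
    if expr.kind != "literal" or not isinstance(expr.payload, int):
        raise TemplateError(f"parameter {key!r} must be an integer")
    return expr.payload


def parse_pattern_token(body: str) -> Pattern:
    """Parse the inside of one ``{...}`` token into a pattern object."""
    body = body.strip()
    if not body:
        raise TemplateError("empty pattern token {}")
    kind, rest = body[0], body[1:]
    if kind not in _KEYS:
        raise TemplateError(
            f"unknown pattern type {kind!r} (expected one of f, r, i)"
        )
    if rest and not rest[0].isspace() and rest[0] != ",":
        raise TemplateError(f"malformed pattern token {{{body}}}")
    params: dict[str, Optional[ValueExpr]] = {}
    for part in _split_params(rest):
        if "=" in part:
            key, _, val = part.partition("=")
            key = key.strip()
            value: Optional[ValueExpr] = _parse_value(val)
        else:
            key, value = part, None  # bare flag
        if key not in _KEYS[kind]:
            raise TemplateError(
                f"unknown parameter {key!r} for pattern type {kind!r}"
            )
        if key in params:
            raise TemplateError(f"duplicate parameter {key!r}")
        params[key] = value

    def flag(key: str) -> bool:
        if key in params:
            if params[key] is not None:
                raise TemplateError(f"{key!r} is a bare flag and takes no value")
            return True
        return False

    required, trim = flag("required"), flag("trim")
    name = _expect_str(params["name"], "name") if params.get("name") else None

    if kind == "f":
        if "pattern" not in params or params["pattern"] is None:
            raise TemplateError("fuzzy pattern requires a pattern = ... parameter")
        src = params["pattern"]
        if src.kind == "literal" and not isinstance(src.payload, str):
            raise TemplateError("fuzzy pattern = must be a string or file reference")
        edits = _expect_int(params["edits"], "edits") if params.get("edits") else 0
        metric = (
            _expect_str(params["metric"], "metric")
            if params.get("metric")
            else "levenshtein"
        )
        overlap = (
            _expect_str(params["overlap"], "overlap")
            if params.get("overlap")
            else "none"
        )
        min_overlap = (
            _expect_int(params["min_overlap"], "min_overlap")
            if params.get("min_overlap")
            else 1
        )
        ngram: Union[str, int] = "auto"
        if params.get("ngram"):
            expr = params["ngram"]
            if expr.kind == "literal" and isinstance(expr.payload, int):
                ngram = expr.payload
            elif expr.kind == "literal" and expr.payload in ("auto", "off"):
                ngram = 0 if expr.payload == "off" else "auto"
            else:
                raise TemplateError('ngram must be an integer, "auto", or "off"')
        return FuzzyPattern(
            source=src,
            max_edits=edits,
            metric=metric,
            required=required,
            trim=trim,
            name=name,
            overlap=overlap,
            min_overlap=min_overlap,
            ngram=ngram,
        )

    char_class = (
        parse_char_class(_expect_str(params["pattern"], "pattern"))
        if params.get("pattern")
        else UNIVERSAL
    )
    if kind == "r":
        if "length" not in params or params["length"] is None:
            raise TemplateError("fixed-length pattern requires length = ...")
        lexpr = params["length"]
        length: Union[int, ValueExpr]
        if lexpr.kind == "literal":
            length = _expect_int(lexpr, "length")
        elif lexpr.kind == "variable_ref":
            length = lexpr
        else:
            raise TemplateError("length must be an integer or variable reference")
        return FixedWildcardPattern(
            length=length, char_class=char_class, trim=trim,
            required=required, name=name,
        )

    # interval pattern
    min_len = _expect_int(params["min"], "min") if params.get("min") else 0
    max_len = _expect_int(params["max"], "max") if params.get("max") else None
    return IntervalPattern(
        min_len=min_len, max_len=max_len, char_class=char_class,
        trim=trim, name=name,
    )


def parse_template(source: str, file_slot: int = 0, base_dir: str = ".") -> TemplateSpec:
    """Parse template text into a :class:`TemplateSpec`.

    Lines keep source order; ``#`` comments and blank lines are skipped.
    """
    if not source.strip():
        raise TemplateError("empty template")
    lines: list[TemplateLine] = []
    for raw in source.splitlines():
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        order: Optional[int] = None
        m = _ORDER_RE.match(stripped)
        if m:
            order = int(m.group(1))
            stripped = stripped[m.end():]
        patterns: list[Pattern] = []
        pos = 0
        for tok in _TOKEN_RE.finditer(stripped):
            if stripped[pos:tok.start()].strip():
                raise TemplateError(
                    f"unexpected text {stripped[pos:tok.start()]!r} outside pattern braces"
                )
            patterns.append(parse_pattern_token(tok.group(1)))
            pos = tok.end()
        if stripped[pos:].strip():
            raise TemplateError(
                f"unexpected text {stripped[pos:]!r} outside pattern braces"
            )
        lines.append(TemplateLine(patterns=tuple(patterns), order_index=order,
                                  file_slot=file_slot))
    return TemplateSpec(lines=tuple(lines), base_dir=base_dir)


def parse_template_file(path: str, file_slot: int = 0) -> TemplateSpec:
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_template(fh.read(), file_slot=file_slot,
                              base_dir=os.path.dirname(os.path.abspath(path)))


def load_list_file(
    path: str,
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS,
    alphabet: Optional[frozenset[str]] = None,
) -> list[Subpattern]:
    """Load subpatterns (one per line, optional TAB-separated name column).

    Entry ``i`` gets ``pattern_idx`` ``i`` (list order); the name defaults to
    the sequence itself.  Characters outside ``alphabet`` (when given) only
    warn — templates are byte-oriented and format-agnostic.
    """
    subs: list[Subpattern] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                raise TemplateError(f"{path}:{lineno}: blank line in list file")
            seq, _, name = line.partition("\t")
            if alphabet is not None:
                bad = sorted(set(seq) - alphabet - wildcard_chars)
                if bad:
                    warnings.warn(
                        f"{path}:{lineno}: characters {bad} outside the "
                        "configured alphabet",
                        stacklevel=2,
                    )
            subs.append(make_subpattern(seq, name or None, wildcard_chars))
    if not subs:
        raise TemplateError(f"list file {path} is empty")
    return subs


class ListFileCache:
    """Loads each list file at most once per run."""

    def __init__(self, base_dir: str = ".",
                 wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS):
        self.base_dir = base_dir
        self.wildcard_chars = wildcard_chars
        self._cache: dict[str, list[Subpattern]] = {}

    def load(self, path: str) -> list[Subpattern]:
        full = path if os.path.isabs(path) else os.path.join(self.base_dir, path)
        if full not in self._cache:
            self._cache[full] = load_list_file(full, self.wildcard_chars)
        return self._cache[full]


def resolve_value(
    expr: ValueExpr,
    vars: VariableStore,
    lists: Optional[ListFileCache] = None,
):
    """Resolve a parameter expression against bound variables and list files.

    Returns the literal itself, the stored variable value, the full subpattern
    list for ``f"path"``, or a single-element list for ``f"path"[selector]``.
    """
    if expr.kind == "literal":
        return expr.payload
    if expr.kind == "variable_ref":
        return vars.lookup(expr.payload)
    if lists is None:
        lists = ListFileCache()
    subs = lists.load(expr.payload)
    if expr.kind == "file_ref":
        return subs
    # file_ref_selected
    sel = resolve_value(expr.selector, vars, lists)
    if not isinstance(sel, int):
        raise TemplateError(f"selector must resolve to an integer, got {sel!r}")
    if not 0 <= sel < len(subs):
        raise VariableError(
            f"selector {sel} out of range for list {expr.payload!r} "
            f"({len(subs)} entries)"
        )
    return [subs[sel]]


# ---------------------------------------------------------------------------
# serialization (round-trip support)

def _fmt_value(expr: ValueExpr) -> str:
    if expr.kind == "literal":
        return str(expr.payload) if isinstance(expr.payload, int) else f'"{expr.payload}"'
    if expr.kind == "variable_ref":
        return f"%{expr.payload}%"
    base = f'f"{expr.payload}"'
    if expr.kind == "file_ref_selected":
        return f"{base}[{_fmt_value(expr.selector)}]"
    return base


def serialize_pattern(p: Pattern) -> str:
    parts: list[str] = []
    if isinstance(p, FuzzyPattern):
        kind = "f"
        if p.required:
            parts.append("required")
        if p.trim:
            parts.append("trim")
        if p.name:
            parts.append(f'name = "{p.name}"')
        if p.max_edits:
            parts.append(f"edits = {p.max_edits}")
        parts.append(f"pattern = {_fmt_value(p.source)}")
        if p.metric != "levenshtein":
            parts.append(f'metric = "{p.metric}"')
        if p.overlap != "none":
            parts.append(f'overlap = "{p.overlap}"')
        if p.min_overlap != 1:
            parts.append(f"min_overlap = {p.min_overlap}")
        if p.ngram != "auto":
            parts.append('ngram = "off"' if p.ngram == 0 else f"ngram = {p.ngram}")
    elif isinstance(p, FixedWildcardPattern):
        kind = "r"
        if p.required:
            parts.append("required")
        if p.trim:
            parts.append("trim")
        if p.name:
            parts.append(f'name = "{p.name}"')
        if isinstance(p.length, int):
            parts.append(f"length = {p.length}")
        else:
            parts.append(f"length = {_fmt_value(p.length)}")
        if not p.char_class.is_universal:
            parts.append(f'pattern = "{p.char_class.source_spec}"')
    else:
        kind = "i"
        if p.trim:
            parts.append("trim")
        if p.name:
            parts.append(f'name = "{p.name}"')
        if p.min_len:
            parts.append(f"min = {p.min_len}")
        if p.max_len is not None:
            parts.append(f"max = {p.max_len}")
        if not p.char_class.is_universal:
            parts.append(f'pattern = "{p.char_class.source_spec}"')
    body = kind if not parts else f"{kind} {', '.join(parts)}"
    return "{" + body + "}"


def serialize_template(spec: TemplateSpec) -> str:
    out = []
    for line in spec.lines:
        prefix = f"{line.order_index} " if line.order_index is not None else ""
        out.append(prefix + "".join(serialize_pattern(p) for p in line.patterns))
    return "\n".join(out) + "\n"


def load_template_set(paths: Sequence[str]) -> TemplateSet:
    """Load one template file per input file into a :class:`TemplateSet`."""
    return TemplateSet(specs=tuple(
        parse_template_file(p, file_slot=i) for i, p in enumerate(paths)
    ))
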