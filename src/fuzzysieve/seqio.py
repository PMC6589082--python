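"""Streaming input/output for line-oriented read files.

The reader is format-agnostic: it groups consecutive lines of each input
file into records of the template's group size (4 for FASTQ), detecting gzip
by magic bytes.  Matched records are routed to per-destination output files
whose names may interpolate ``%name.field%`` variables bound during the
match (the generalization of demultiplexing); unmatched records pass through
byte-identical to an unmatched file.

Processing follows a producer-consumer layout: the main thread reads batches
of records, worker threads match them independently, and finished batches
are written out under a lock as soon as they are done.  Per-destination
output is therefore guaranteed only as a multiset of records for
``workers > 1``; sequential mode (``workers=1`` or ``preserve_order=True``)
keeps input order.  A bounded number of in-flight batches caps memory.
"""

from __future__ import annotations

import gzip
import os
import re
import threading
from collections import OrderedDict
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

from .engine import RecordResult
from .errors import InputError, VariableError
from .variables import VariableStore

_GZIP_MAGIC = b"\x1f\x8b"
_PLACEHOLDER_RE = re.compile(r"%([A-Za-z_][\w.]*)%")


@dataclass(frozen=True)
class ReadGroup:
    """One record: ``group_size`` raw lines per input file, plus its ordinal."""

    lines: tuple[tuple[str, ...], ...]
    ordinal: int


def open_text(path: Union[str, os.PathLike], mode: str = "rt"):
    """Open a text file, transparently decoding gzip (by magic bytes when
    reading, by ``.gz`` suffix when writing)."""
    path = os.fspath(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == _GZIP_MAGIC:
            return gzip.open(path, mode, encoding="utf-8", newline="")
        return open(path, mode, encoding="utf-8", newline="")
    parent = os.path.dirname(path)
    if parent:
        os.makedirs(parent, exist_ok=True)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8", newline="\n")
    return open(path, mode, encoding="utf-8", newline="\n")


def _iter_lines(path) -> Iterator[str]:
    with open_text(path) as fh:
        for line in fh:
            yield line.rstrip("\r\n")  # tolerate \n and \r\n


def read_groups(
    paths: Sequence[Union[str, os.PathLike]],
    group_size: Union[int, Sequence[int]],
) -> Iterator[ReadGroup]:
    """Stream fixed-size line groups from one or more parallel input files.

    ``group_size`` may be one integer for all files or one per file.  Raises
    :class:`InputError` on a ragged tail (total lines not a multiple of the
    group size) or when paired files hold unequal record counts.
    """
    if isinstance(group_size, int):
        sizes = [group_size] * len(paths)
    else:
        sizes = list(group_size)
        if len(sizes) != len(paths):
            raise InputError(
                f"{len(paths)} input files but {len(sizes)} group sizes"
            )
    if not paths:
        raise InputError("no input files")
    iters = [_iter_lines(p) for p in paths]
    ordinal = 0
    while True:
        group: list[tuple[str, ...]] = []
        exhausted: list[bool] = []
        for path, size, it in zip(paths, sizes, iters):
            lines: list[str] = []
            for _ in range(size):
                try:
                    lines.append(next(it))
                except StopIteration:
                    break
            if lines and len(lines) < size:
                raise InputError(
                    f"{os.fspath(path)}: ragged tail — record {ordinal + 1} has "
                    f"{len(lines)} lines near line {ordinal * size + len(lines)}, "
                    f"expected {size}"
                )
            exhausted.append(not lines)
            group.append(tuple(lines))
        if all(exhausted):
            return
        if any(exhausted):
            done = [os.fspath(p) for p, e in zip(paths, exhausted) if e]
            raise InputError(
                f"paired input files have unequal record counts: "
                f"{', '.join(done)} ended at record {ordinal}"
            )
        yield ReadGroup(lines=tuple(group), ordinal=ordinal)
        ordinal += 1


def interpolate_filename(template: str, vars: VariableStore) -> str:
    """Replace ``%name.field%`` placeholders with bound values; substituted
    values are sanitized so they cannot escape into other directories."""

    def sub(m: re.Match) -> str:
        value = str(vars.lookup(m.group(1)))
        return value.replace("/", "_").replace("\\", "_").replace(os.sep, "_")

    try:
        return _PLACEHOLDER_RE.sub(sub, template)
    except VariableError as exc:
        raise VariableError(f"in output path {template!r}: {exc}") from exc


class OutputRoute:
    """Routes records to matched/unmatched destinations per input file.

    Keeps at most ``max_open_files`` handles, reopening evicted files in
    append mode, since demultiplexing can produce more destinations than the
    OS handle limit allows.
    """

    def __init__(
        self,
        matched_templates: Sequence[str],
        unmatched_paths: Sequence[str],
        max_open_files: int = 64,
    ):
        if len(matched_templates) != len(unmatched_paths):
            raise InputError("need one matched template and one unmatched path "
                             "per input file")
        self.matched_templates = list(matched_templates)
        self.unmatched_paths = list(unmatched_paths)
        self.max_open_files = max_open_files
        self._handles: "OrderedDict[str, object]" = OrderedDict()
        self._seen: set[str] = set()
        self.counts: dict[str, int] = {}

    def _handle(self, path: str):
        if path in self._handles:
            self._handles.move_to_end(path)
            return self._handles[path]
        mode = "at" if path in self._seen else "wt"
        if len(self._handles) >= self.max_open_files:
            _, fh = self._handles.popitem(last=False)
            fh.close()
        handle = open_text(path, mode)
        self._handles[path] = handle
        self._seen.add(path)
        return handle

    def write(self, path: str, lines: Iterable[str]) -> None:
        fh = self._handle(path)
        for line in lines:
            fh.write(line)
            fh.write("\n")
        self.counts[path] = self.counts.get(path, 0) + 1

    def route(self, result: RecordResult) -> None:
        """Write one record: trimmed lines to the interpolated matched path,
        or the original lines to the unmatched path."""
        for slot, lines in enumerate(result.output_lines):
            if result.matched:
                path = interpolate_filename(
                    self.matched_templates[slot], result.variables)
            else:
                path = self.unmatched_paths[slot]
            self.write(path, lines)

    def close(self) -> None:
        for fh in self._handles.values():
            fh.close()
        self._handles.clear()

    def __enter__(self) -> "OutputRoute":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def route_record(result: RecordResult, routes: OutputRoute) -> None:
    """Function-style alias for :meth:`OutputRoute.route`."""
    routes.route(result)


@dataclass
class RunStats:
    """Counters accumulated over one processing run."""

    records: int = 0
    matched: int = 0
    unmatched: int = 0
    per_destination: dict[str, int] = field(default_factory=dict)


def _chunked(groups: Iterable[ReadGroup], size: int) -> Iterator[list[ReadGroup]]:
    batch: list[ReadGroup] = []
    for g in groups:
        batch.append(g)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def process_batches(
    groups: Iterable[ReadGroup],
    process: Callable[[ReadGroup], RecordResult],
    routes: OutputRoute,
    worker_count: int = 1,
    batch_size: int = 64,
    preserve_order: bool = False,
    max_pending_batches: Optional[int] = None,
) -> RunStats:
    """Match and route records in batches.

    Each record is processed independently.  Per-destination content as a
    multiset of records is identical for any ``worker_count``/``batch_size``;
    with one worker (or ``preserve_order``) output order equals input order.
    A worker failure propagates as the original exception.
    """
    if worker_count < 1 or batch_size < 1:
        raise InputError("worker_count and batch_size must be >= 1")
    stats = RunStats()
    write_lock = threading.Lock()

    def emit(results: Sequence[RecordResult]) -> None:
        with write_lock:
            for result in results:
                stats.records += 1
                if result.matched:
                    stats.matched += 1
                else:
                    stats.unmatched += 1
                routes.route(result)

    if worker_count == 1 or preserve_order:
        for batch in _chunked(groups, batch_size):
            emit([process(g) for g in batch])
    else:
        if max_pending_batches is None:
            max_pending_batches = 4 * worker_count
        with ThreadPoolExecutor(max_workers=worker_count) as pool:
            pending = set()
            for batch in _chunked(groups, batch_size):
                while len(pending) >= max_pending_batches:
                    done, pending = wait(pending, return_when=FIRST_COMPLETED)
                    for fut in done:
                        emit(fut.result())
                pending.add(pool.submit(lambda b: [process(g) for g in b], batch))
            for fut in pending:
                emit(fut.result())
    stats.per_destination = dict(routes.counts)
    return stats
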