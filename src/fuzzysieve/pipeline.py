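"""High-level demultiplexing/trimming runs: templates in, routed files out."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .dsl import load_template_set
from .engine import MatchEngine
from .errors import InputError
from .patterns import DEFAULT_WILDCARDS
from .seqio import OutputRoute, ReadGroup, RunStats, process_batches, read_groups


def expand_output_paths(spec: Union[str, Sequence[str]], n_inputs: int) -> list[str]:
    """One output path (template) per input file.

    A single path with multiple inputs gets ``_1``/``_2``/... inserted before
    its extension (``reads.fastq.gz`` -> ``reads_1.fastq.gz``).
    """
    if not isinstance(spec, str):
        paths = list(spec)
        if len(paths) == n_inputs:
            return paths
        if len(paths) != 1:
            raise InputError(
                f"{len(paths)} output paths for {n_inputs} input files"
            )
        spec = paths[0]
    if n_inputs == 1:
        return [spec]
    base = spec
    exts = ""
    while True:
        root, ext = os.path.splitext(base)
        if ext.lower() in (".gz", ".fastq", ".fq", ".txt", ".fasta", ".fa"):
            base, exts = root, ext + exts
        else:
            break
    return [f"{base}_{i + 1}{exts}" for i in range(n_inputs)]


@dataclass
class RunConfig:
    """Everything one processing run needs."""

    input_paths: Sequence[str]
    template_paths: Sequence[str]  # one per input, order-aligned
    matched: Union[str, Sequence[str]] = "matched.fastq"
    unmatched: Union[str, Sequence[str]] = "unmatched.fastq"
    worker_count: int = 1
    batch_size: int = 64
    preserve_order: bool = False
    ngram_override: Optional[int] = None
    wildcard_chars: frozenset[str] = DEFAULT_WILDCARDS
    max_open_files: int = 64

    def __post_init__(self):
        if len(self.template_paths) != len(self.input_paths):
            raise InputError(
                f"{len(self.input_paths)} input files need "
                f"{len(self.input_paths)} template files, got "
                f"{len(self.template_paths)}"
            )
        if self.worker_count < 1:
            raise InputError("worker count must be >= 1")


def run_pipeline(config: RunConfig) -> RunStats:
    """Parse templates, match every record of the inputs, and route output."""
    tset = load_template_set(config.template_paths)
    engine = MatchEngine(
        tset,
        wildcard_chars=config.wildcard_chars,
        ngram_override=config.ngram_override,
    )
    n = len(config.input_paths)
    matched = expand_output_paths(config.matched, n)
    unmatched = expand_output_paths(config.unmatched, n)
    groups = read_groups(
        config.input_paths, [spec.group_size for spec in tset.specs])

    def process(group: ReadGroup):
        return engine.match_record(group.lines)

    with OutputRoute(matched, unmatched, config.max_open_files) as routes:
        return process_batches(
            groups, process, routes,
            worker_count=config.worker_count,
            batch_size=config.batch_size,
            preserve_order=config.preserve_order,
        )


def demultiplex(
    inputs: Sequence[str],
    templates: Sequence[str],
    matched: Union[str, Sequence[str]],
    unmatched: Union[str, Sequence[str]],
    **options,
) -> RunStats:
    """Convenience wrapper: run a full demultiplexing/trimming pass."""
    return run_pipeline(RunConfig(
        input_paths=list(inputs), template_paths=list(templates),
        matched=matched, unmatched=unmatched, **options,
    ))
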