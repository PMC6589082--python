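"""Synthetic benchmarks with ground truth, and the difference metric.

Two read simulators mirror the package's evaluation setups:

* **adapter trimming** — reads of ~130 nt where, with probability 0.75, a
  single shared random 30-mer adapter sits at the 3' end (50% exact, 50%
  carrying one random edit); reads without the adapter are fully random.
* **demultiplexing** — 48 random 5' barcodes of length 8-15; each read has
  probability 0.5 of starting with one barcode (again at most one edit)
  followed by 100 random nucleotides, and is otherwise 100 random
  nucleotides.

Edits are placed uniformly inside the feature.  Insertions go *after* one of
the feature's characters (positions 1..L), never before the first: an
insertion ahead of a 5' barcode is indistinguishable from longer upstream
context — it moves the feature rather than altering it — and would make
anchored recovery ill-posed.

The RNG stream layout is fixed: stream ``[seed, 0]`` draws the shared
features (adapter, barcode set) and stream ``[seed, 1, i]`` drives read
``i`` alone, so growing ``read_count`` never reshuffles earlier reads.

For controlled-recovery experiments the barcode set can be constrained by
*anchored cross-distance*: the minimum Levenshtein distance between any
prefix of one barcode and the full other barcode (minimized over both
orders).  Plain pairwise distance is not enough when lengths vary — a short
barcode equal to a prefix of a longer one keeps a large full distance yet
still captures the longer barcode's reads under 5'-anchored matching.  An
anchored cross-distance of at least ``2k + 2`` makes assignment at ``k``
edits unambiguous.

The difference percentage aggregates demultiplexing errors over barcodes:

    D = (sum_b wrong_b + missing_b) / with_barcode

where ``wrong_b`` counts reads placed in barcode ``b``'s file that do not
belong there, ``missing_b`` counts reads of ``b`` absent from its file, and
``with_barcode`` is the number of reads truly carrying any barcode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError
from .seqio import open_text

EDIT_KINDS = ("sub", "ins", "del")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset.

    ``edit_profile`` gives the probabilities of injecting 0 or 1 edit into a
    feature-bearing read; ``feature_fraction`` the probability that a read
    carries the feature at all.
    """

    read_count: int
    seed: int = 0
    alphabet: str = "ACGT"
    read_length: int = 130
    feature_fraction: float = 0.75
    edit_profile: tuple[float, float] = (0.5, 0.5)
    edit_kinds: tuple[str, ...] = EDIT_KINDS
    adapter_length: int = 30
    barcode_count: int = 48
    barcode_length_range: tuple[int, int] = (8, 15)
    insert_length: int = 100  # random nucleotides after a 5' barcode
    min_cross_distance: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.feature_fraction <= 1.0:
            raise InputError("feature_fraction must be in [0, 1]")
        if abs(sum(self.edit_profile) - 1.0) > 1e-9:
            raise InputError("edit_profile probabilities must sum to 1")
        if any(k not in EDIT_KINDS for k in self.edit_kinds):
            raise InputError(f"edit kinds must be among {EDIT_KINDS}")


def adapter_spec(read_count: int, seed: int = 0, **overrides) -> SimSpec:
    """The 3' adapter benchmark conditions: ~130 nt reads, 75% carrying a
    30 nt adapter, half exact and half with one edit."""
    return SimSpec(read_count=read_count, seed=seed, **overrides)


def demux_spec(read_count: int, seed: int = 0, **overrides) -> SimSpec:
    """The demultiplexing benchmark conditions: 48 barcodes of length 8-15,
    half the reads starting with one barcode (at most one edit) followed by
    100 random nucleotides."""
    overrides.setdefault("feature_fraction", 0.5)
    return SimSpec(read_count=read_count, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# primitive draws


def _rand_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def mutate_once(
    seq: str,
    rng: np.random.Generator,
    alphabet: str,
    kinds: Sequence[str] = EDIT_KINDS,
) -> str:
    """Apply exactly one random edit; the result is always at Levenshtein
    distance 1 from ``seq``."""
    kind = kinds[int(rng.integers(0, len(kinds)))]
    L = len(seq)
    if kind == "sub":
        pos = int(rng.integers(0, L))
        others = [c for c in alphabet if c != seq[pos]]
        return seq[:pos] + others[int(rng.integers(0, len(others)))] + seq[pos + 1:]
    if kind == "ins":
        while True:
            pos = int(rng.integers(1, L + 1))  # after a feature character
            ch = alphabet[int(rng.integers(0, len(alphabet)))]
            out = seq[:pos] + ch + seq[pos:]
            # an insertion inside the leading run of identical characters is
            # string-identical to inserting before position 0, which merely
            # shifts the feature; redraw those
            if out[1:] != seq:
                return out
    pos = int(rng.integers(0, L))  # deletion
    return seq[:pos] + seq[pos + 1:]


def _draw_edits(rng: np.random.Generator, profile: tuple[float, float]) -> int:
    return 0 if rng.random() < profile[0] else 1


# ---------------------------------------------------------------------------
# anchored cross-distance (barcode set constraint)


def levenshtein_matrix(a: str, b: str) -> np.ndarray:
    """Full (len(a)+1) x (len(b)+1) edit-distance matrix."""
    la, lb = len(a), len(b)
    M = np.zeros((la + 1, lb + 1), dtype=np.int64)
    M[:, 0] = np.arange(la + 1)
    M[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            M[i, j] = min(M[i - 1, j - 1] + cost, M[i - 1, j] + 1, M[i, j - 1] + 1)
    return M


def anchored_cross_distance(a: str, b: str) -> int:
    """min over prefixes of either string vs the full other string of their
    Levenshtein distance.  Bounded above by the plain pairwise distance."""
    M = levenshtein_matrix(a, b)
    return int(min(M[:, len(b)].min(), M[len(a), :].min()))


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one read: the injected feature (``None`` when
    absent), its edit count, and the mutated region as embedded."""

    read_id: str
    feature: Optional[str]  # barcode name, or "adapter"
    edits: int
    region: Optional[str] = None


@dataclass(frozen=True)
class AdapterDataset:
    fastq_path: str
    list_path: str
    truth_path: str
    adapter: str
    truth: tuple[TruthRow, ...]


@dataclass(frozen=True)
class DemuxDataset:
    fastq_path: str
    list_path: str
    truth_path: str
    barcodes: tuple[str, ...]
    names: tuple[str, ...]
    truth: tuple[TruthRow, ...]


def _write_fastq(path: str, reads: Sequence[tuple[str, str]]) -> None:
    with open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _write_truth(path: str, truth: Sequence[TruthRow]) -> None:
    with open_text(path, "wt") as fh:
        fh.write("read_id\tfeature\tedits\n")
        for row in truth:
            fh.write(f"{row.read_id}\t{row.feature or '-'}\t{row.edits}\n")


def gen_adapter_dataset(spec: SimSpec, out_dir: str) -> AdapterDataset:
    """Generate the 3' adapter benchmark: FASTQ + single-entry list file +
    truth table.  Deterministic under ``spec.seed``."""
    if spec.adapter_length > spec.read_length:
        raise InputError("adapter longer than the read length")
    os.makedirs(out_dir, exist_ok=True)
    rng0 = np.random.default_rng([spec.seed, 0])
    adapter = _rand_seq(rng0, spec.alphabet, spec.adapter_length)
    pad = spec.read_length - spec.adapter_length
    reads: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for i in range(spec.read_count):
        rng = np.random.default_rng([spec.seed, 1, i])
        rid = f"read{i}"
        if rng.random() < spec.feature_fraction:
            edits = _draw_edits(rng, spec.edit_profile)
            region = adapter if edits == 0 else mutate_once(
                adapter, rng, spec.alphabet, spec.edit_kinds)
            seq = _rand_seq(rng, spec.alphabet, pad) + region
            truth.append(TruthRow(rid, "adapter", edits, region))
        else:
            seq = _rand_seq(rng, spec.alphabet, spec.read_length)
            truth.append(TruthRow(rid, None, 0))
        reads.append((rid, seq))
    fastq = os.path.join(out_dir, "reads.fastq")
    lst = os.path.join(out_dir, "adapter.txt")
    tr = os.path.join(out_dir, "truth.tsv")
    _write_fastq(fastq, reads)
    with open_text(lst, "wt") as fh:
        fh.write(f"{adapter}\tadapter\n")
    _write_truth(tr, truth)
    return AdapterDataset(fastq, lst, tr, adapter, tuple(truth))


def generate_barcodes(spec: SimSpec) -> tuple[str, ...]:
    """Draw the barcode set; with ``min_cross_distance`` set, rejection-sample
    until every pair's anchored cross-distance meets the bound."""
    rng = np.random.default_rng([spec.seed, 0])
    lo, hi = spec.barcode_length_range
    barcodes: list[str] = []
    attempts = 0
    limit = 2000 * spec.barcode_count
    while len(barcodes) < spec.barcode_count:
        attempts += 1
        if attempts > limit:
            raise InputError(
                f"could not draw {spec.barcode_count} barcodes with anchored "
                f"cross-distance >= {spec.min_cross_distance} after {limit} tries"
            )
        length = int(rng.integers(lo, hi + 1))
        cand = _rand_seq(rng, spec.alphabet, length)
        if spec.min_cross_distance is not None:
            if any(
                anchored_cross_distance(cand, b) < spec.min_cross_distance
                for b in barcodes
            ):
                continue
        if cand in barcodes:
            continue
        barcodes.append(cand)
    return tuple(barcodes)


def gen_demux_dataset(spec: SimSpec, out_dir: str) -> DemuxDataset:
    """Generate the demultiplexing benchmark: FASTQ + barcode list file (TAB
    name column) + truth table.  Deterministic under ``spec.seed``."""
    os.makedirs(out_dir, exist_ok=True)
    barcodes = generate_barcodes(spec)
    names = tuple(f"BC{i + 1:02d}" for i in range(len(barcodes)))
    reads: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for i in range(spec.read_count):
        rng = np.random.default_rng([spec.seed, 1, i])
        rid = f"read{i}"
        if rng.random() < spec.feature_fraction:
            idx = int(rng.integers(0, len(barcodes)))
            edits = _draw_edits(rng, spec.edit_profile)
            region = barcodes[idx] if edits == 0 else mutate_once(
                barcodes[idx], rng, spec.alphabet, spec.edit_kinds)
            seq = region + _rand_seq(rng, spec.alphabet, spec.insert_length)
            truth.append(TruthRow(rid, names[idx], edits, region))
        else:
            seq = _rand_seq(rng, spec.alphabet, spec.insert_length)
            truth.append(TruthRow(rid, None, 0))
        reads.append((rid, seq))
    fastq = os.path.join(out_dir, "reads.fastq")
    lst = os.path.join(out_dir, "barcodes.txt")
    tr = os.path.join(out_dir, "truth.tsv")
    _write_fastq(fastq, reads)
    with open_text(lst, "wt") as fh:
        for bc, name in zip(barcodes, names):
            fh.write(f"{bc}\t{name}\n")
    _write_truth(tr, truth)
    return DemuxDataset(fastq, lst, tr, barcodes, names, tuple(truth))


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class DifferenceReport:
    """Per-barcode wrong/missing counts and the aggregate difference D."""

    wrong: Mapping[str, int]
    missing: Mapping[str, int]
    with_barcode: int
    D: float

    @property
    def percent(self) -> float:
        return 100.0 * self.D


def difference_metric(
    truth: Mapping[str, Optional[str]],
    assignments: Mapping[str, Optional[str]],
) -> DifferenceReport:
    """Score observed per-read barcode assignments against the truth.

    A barcode-free read assigned to ``b`` counts once in ``wrong_b``; a
    barcode-bearing read assigned to the wrong ``b'`` counts in ``wrong_b'``
    and in ``missing_b`` of its true barcode; an unassigned barcode-bearing
    read counts in ``missing_b`` only.
    """
    extra = set(assignments) - set(truth)
    if extra:
        raise InputError(f"assignments for unknown read ids: {sorted(extra)[:5]}")
    wrong: dict[str, int] = {}
    missing: dict[str, int] = {}
    with_barcode = 0
    for rid, true_b in truth.items():
        assigned = assignments.get(rid)
        if true_b is not None:
            with_barcode += 1
            if assigned != true_b:
                missing[true_b] = missing.get(true_b, 0) + 1
        if assigned is not None and assigned != true_b:
            wrong[assigned] = wrong.get(assigned, 0) + 1
    if with_barcode == 0:
        raise InputError("difference metric undefined: no read carries a barcode")
    total = sum(wrong.values()) + sum(missing.values())
    return DifferenceReport(
        wrong=wrong, missing=missing, with_barcode=with_barcode,
        D=total / with_barcode,
    )


def read_truth(path: str) -> dict[str, Optional[str]]:
    """Load a truth table written by the generators: read_id -> feature."""
    out: dict[str, Optional[str]] = {}
    with open_text(path) as fh:
        header = next(fh)
        for line in fh:
            rid, feature, _edits = line.rstrip("\n").split("\t")
            out[rid] = None if feature == "-" else feature
    return out


def collect_assignments(
    out_dir: str,
    prefix: str = "matched_",
    suffix: str = ".fastq",
    group_size: int = 4,
) -> dict[str, str]:
    """Recover read -> barcode assignments from routed output files named
    ``<prefix><barcode><suffix>`` (read ids taken from the header lines)."""
    assignments: dict[str, str] = {}
    for name in sorted(os.listdir(out_dir)):
        if not (name.startswith(prefix) and name.endswith(suffix)):
            continue
        barcode = name[len(prefix):len(name) - len(suffix)]
        with open_text(os.path.join(out_dir, name)) as fh:
            for lineno, line in enumerate(fh):
                if lineno % group_size == 0:
                    rid = line.rstrip("\n")[1:].split()[0]
                    assignments[rid] = barcode
    return assignments
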