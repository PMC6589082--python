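# Methods

This note documents the models and algorithmic choices behind `fuzzysieve`:
what each component computes, the parameters that matter, the numerical and
tie-breaking conventions, what the synthetic benchmarks do and do not
emulate, and known limitations.

## Template semantics

A template set holds one template per input file; each template's lines are
matched against consecutive groups of that many input lines (4 for FASTQ).
Lines are evaluated in *processing order*: lines with an explicit leading
integer first, ascending, then unindexed lines in source order. A record
matches iff every line matches; trimming is applied only then, and unmatched
records are emitted byte-identical — demultiplexing must never corrupt reads
it cannot explain.

Named patterns bind `{length, pattern_idx, pattern_name, edits}` when their
line succeeds. Bindings are visible to later patterns on the same line and
to lines with a later processing order; a failed line or failed candidate
attempt leaves no bindings behind (attempts stage their bindings in an
overlay store committed only on acceptance). Fixed- and interval-wildcard
patterns bind `{length, edits=0}`; an interval pattern's name is honored
only when it is the sole pattern of its chunk, because the tiling DP decides
*whether* a chunk tiles a segment, not which segmentation was used — only
chunk-level spans exist (and likewise `trim` on an interval pattern trims
the whole chunk's span).

Templates are byte-oriented: no DNA-specific validation is applied anywhere,
so any line-oriented text format can be processed. The wildcard character
set defaults to `{'N'}` (the undetermined base) and is configurable; a
wildcard in pattern or text matches anything at zero cost.

## Fuzzy matching

Three metrics are supported per fuzzy pattern: Hamming (substitutions
only), Levenshtein (insertions/deletions/substitutions, the default), and
restricted Damerau–Levenshtein. The Damerau variant is the *optimal string
alignment* form — adjacent transpositions cost one edit and each character
participates in at most one transposition — chosen because it is the
standard transposition model for read errors and keeps the same DP shape.

The Levenshtein/OSA searcher is the classic semi-global DP over text
columns. Ukkonen's cutoff tracks the deepest pattern row still within the
edit budget `k` and computes only one row past it per column; results are
identical to the full DP (asserted bitwise in tests) with expected cost
O(k·|T|) per subpattern. The DP-over-bit-vector alternatives are
deliberately not used: the engine needs per-match length information for
variable binding and trimming, which bit-parallel formulations do not
retain.

**One candidate per end position.** For every text end with a within-budget
alignment the searcher reports the minimal edit count and the *longest* text
span achieving it (the smallest start). The minimal start is propagated
through the DP alongside the distance (each cell keeps the minimum start
over its optimal predecessors); a greedy traceback with a fixed move
preference cannot guarantee the longest span and would, for example, report
a shifted 1-edit barcode as starting at position 1, breaking 5'-anchored
templates. Candidate streams from multiple subpatterns are merged ordered
by (end, edits, subpattern index), all ascending — deterministic and
leftmost-first.

**Overlap at line ends.** A fuzzy pattern may be allowed to overhang the
start and/or end of the line (`overlap = "start"|"end"|"both"`); overhanging
pattern characters cost nothing. `min_overlap` (default 1) requires that
many in-text characters for a match touching an overlap-enabled end, which
suppresses degenerate empty matches. Overlap at the start only applies when
the search begins at the line start.

**Hamming via Bitap.** The shift-and formulation keeps `k+1` state vectors;
masks and states are genuinely split into ⌈|P|/w⌉ machine words with
carry-propagating shifts (w defaults to 63 and is configurable; correctness
does not depend on it). Matches always have length |P|.

**n-gram pre-elimination.** A subpattern P can be eliminated without DP if
|P| > (k+1)(n−1)+k and none of its n-grams occurs in the text: with at most
k edits splitting the occurrence, at least one length-n block survives
intact, so absence of all grams certifies absence of any within-k
occurrence. The engine's automatic size is the largest n satisfying
n < (|P|−k)/(k+1)+1, minimized over the pattern's subpatterns; for a 30 nt
adapter at k=1 this gives 15. Subpatterns below the length threshold,
subpatterns containing wildcards, and all subpatterns when the text contains
a wildcard character, always survive (n-grams cannot see wildcards). The
filter is an optimization only; tests assert the candidate stream is
unchanged with it disabled.

## Wildcard matching

Fixed-length wildcards are a sliding window: position `at` matches iff
`at+L ≤ |T|` and all window characters are in the class, O(L) per probe.

Consecutive interval wildcards are matched jointly. With f(i, j) = "patterns
1..j tile the first i characters", the naive recursion sums f(·, j−1) over
every admissible split and re-scans the run, which is cubic. Two standard
devices reduce it to O(|patterns|·length): the run-length table
l(i, j) (longest suffix ending at i allowed by pattern j, updated
incrementally) and per-pattern prefix sums p(i, j) of f, giving

    f(i, j) = p(i − min_j, j−1) − p(max(i − max_j, i − l(i, j)) − 1, j−1)

with out-of-range prefix-sum indices contributing zero (the clamping is made
explicit here; an unbounded max_j behaves as max_j = i so the window stays
finite). f is stored saturated to {0, 1}: only f ≠ 0 is ever queried and
saturation keeps the prefix sums small without changing any query. All
public indices are 0-based half-open; the tables use the 1-based prefix
convention internally, converted at exactly one boundary.

The tables live in an `IntervalDPState` anchored at a fixed text index and
extend their frontier incrementally — the greedy matcher probes many end
positions for the same anchor, and extension never recomputes or changes an
existing row, so the amortized cost of all probes for one chunk is linear in
the text.

## The greedy line matcher

A line's patterns are partitioned into maximal alternating chunks of
interval patterns and of fixed-length patterns (fuzzy + fixed wildcards),
with an implicit empty interval chunk anchoring the line start, and — when
the line ends with a fixed chunk — an implicit empty one anchoring the end.

For each (interval chunk, fixed chunk) pair, starting patterns are drawn
from the chunk's leading optional prefix plus its first required pattern.
Each candidate of the starting pattern (ascending end, then edits, then
subpattern index) anchors a greedy left-to-right match of the chunk's
remaining patterns — fuzzy tail patterns take their lowest-edit anchored
candidate, optional tail patterns that fail are skipped — and is accepted
iff the preceding interval chunk tiles the text between the cursor and the
candidate start. For the final pair the trailing interval chunk must also
tile the remainder of the line; folding that check into candidate
acceptance is what makes 3'-anchored templates work, since the matcher
never backtracks across an accepted pair. A fixed chunk that is entirely
optional and never matches is skipped, merging its flanking interval
chunks. If a required pattern has no viable candidate the line fails
immediately.

Greediness is a deliberate trade: the matcher can reject lines an
exhaustive segmentation search would accept (the test suite pins one such
adversarial fixture), in exchange for linear-time scanning and early
termination. Two caches — anchored per-position results for fixed-chunk
tails, and the incremental interval DP state — are pure optimizations;
tests assert results are identical with both disabled.

## IO and parallelism

The reader is format-agnostic line grouping with gzip detected by magic
bytes; a ragged tail (line count not a multiple of the group size) or
unequal paired record counts abort with a diagnostic naming the file.
Output routing interpolates `%name.field%` into destination paths
(substituted values are sanitized of path separators), keeps a bounded LRU
pool of open handles (barcode counts can exceed OS limits), and appends on
reopen. Input tolerates `\n` and `\r\n`; output always writes `\n`.

Records are independent, so processing is batched producer–consumer:
workers match batches, finished batches are written under a lock as they
complete. The contract is multiset equality of per-destination content for
any worker count and batch size; order equals input order in sequential
mode (`workers=1` or `--preserve-order`). In-flight memory is bounded by a
pending-batch cap. CPython threads do not speed up the pure-Python DP, but
the batching structure and its determinism contract are part of the design
and are tested as such.

## Synthetic benchmarks

The generators reproduce two standard evaluation setups with ground truth:

* **Adapter**: reads of ~130 nt; 75% carry one shared random 30-mer adapter
  at the 3' end; a carrier's adapter is exact with probability 0.5 and
  carries exactly one edit otherwise. Non-carriers are 130 random nt;
  carriers are 100 random nt plus the (possibly 1-edit) adapter, so indels
  leave total length 129–131.
* **Demultiplexing**: 48 random barcodes with lengths uniform in [8, 15];
  each read is, with probability 0.5, a (possibly 1-edit) barcode followed
  by 100 random nt, and 100 random nt otherwise.

Edits are placed uniformly inside the feature; substitutions always change
the base. Insertions are drawn after one of the feature's characters
(positions 1..L) and redrawn if the result merely prepends a copy of the
first character: both cases are string-identical to inserting *before* the
feature, which shifts it rather than edits it and would make anchored
recovery ill-posed. With that convention every 1-edit read retains a
minimal-edit alignment flush with the feature's anchored end, which is what
the recovery guarantees below rely on.

The RNG stream layout is fixed — stream `[seed, 0]` for shared features,
`[seed, 1, i]` for read `i` — so increasing the read count never changes
earlier reads, and identical seeds give byte-identical files.

**Controlled recovery and anchored cross-distance.** For the exact-recovery
benchmark the barcode set is rejection-sampled under a constraint stronger
than plain pairwise distance: the *anchored cross-distance* — the minimum
Levenshtein distance between any prefix of one barcode and the full other
barcode, over both orders — must be ≥ 4. Plain pairwise distance is not
sufficient when lengths vary: a short barcode equal to a prefix of a longer
one has full distance ≥ 4 yet captures the longer barcode's reads under
5'-anchored matching. With anchored cross-distance ≥ 2k + 2 and at most k
injected edits, a wrong barcode can match no prefix of a barcoded read
within k edits (triangle inequality through the ≤ k-edit mutation, with one
spare edit for the boundary), so every barcode-bearing read is assigned to
its true barcode and the difference percentage over those reads is exactly
zero. Barcode-*free* reads can still rarely resemble a short barcode at the
5' end, which is why the exact-zero claim is stated over barcode-bearing
reads.

The difference percentage aggregates demultiplexing errors as
D = Σ_b (wrong_b + missing_b) / with_barcode: a barcode-free read assigned
to b counts once in wrong_b; a read of b assigned to b' counts in wrong_b'
and missing_b; an unassigned read of b counts in missing_b only.

**What the simulations do not emulate**: quality-score error models,
position-dependent or instrument-specific error profiles, multiple edits per
feature, chimeric or adapter-dimer reads, and paired-end synthesis. Passing
the benchmarks therefore demonstrates the matching engine's correctness
under its stated error model, not end-to-end performance on any particular
instrument's data.

## Problem sizes

The test suite runs the adapter benchmark at 50,000 reads and the controlled
demultiplexing benchmark at 20,000 reads; the concurrency contract uses
5,000 reads, and the exhaustive oracle suites enumerate small domains
(patterns ≤ 3 over a binary alphabet against texts ≤ 5, plus seeded random
sweeps over the larger domain). `scripts/acceptance.py` uses 20,000 and
10,000 reads respectively — sizes chosen so a complete from-scratch run
stays in the minutes range on a single CPU while keeping the binomial
fractions tight.

## Known limitations

* Binary formats (BAM) cannot be processed; only line-oriented text.
* Multi-line FASTA is out of scope: records must have a fixed line count.
* Quality scores are never interpreted; no quality trimming or filtering.
* The greedy matcher is not optimal; adversarial templates can fail where
  an exhaustive search would succeed (documented and tested).
* Arithmetic in parameter expressions is not supported, only literals,
  variable references, and list-file selection.
* Error messages are generic by construction — the engine knows patterns,
  not biology.
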