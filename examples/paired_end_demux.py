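"""Paired-end demultiplexing with combinatorial barcodes.

The forward template matches a barcode from f.txt; the reverse template
uses the selection operator f"r.txt"[%f.pattern_idx%] so only the reverse
barcode *paired with* the matched forward barcode is accepted.  Line order
indices (1-4) make the reverse read match after the forward read, when the
forward variables already exist.
"""

import os
import tempfile

from fuzzysieve import demultiplex

FWD = """\
{{i}}
1 {{f required, trim, name = "f", edits = 1, pattern = f"{flist}"}}{{i}}
{{i}}
2 {{r trim, length = %f.length%}}{{i}}
"""
REV = """\
{{i}}
3 {{f required, trim, name = "r", edits = 1, pattern = f"{rlist}"[%f.pattern_idx%]}}{{i}}
{{i}}
4 {{r trim, length = %r.length%}}{{i}}
"""

FWD_BC = [("AAAACCCC", "F1"), ("GGGGTTTT", "F2")]
REV_BC = [("TTTTGGGG", "R1"), ("CCCCAAAA", "R2")]

PAIRS = [
    ("good1", "AAAACCCC", "TTTTGGGG"),  # F1/R1 concordant
    ("good2", "GGGGTTTT", "CCCCAAAA"),  # F2/R2 concordant
    ("bad1", "AAAACCCC", "CCCCAAAA"),   # F1 with R2: discordant
]

with tempfile.TemporaryDirectory() as work:
    def path(name):
        return os.path.join(work, name)

    with open(path("f.txt"), "w") as fh:
        fh.writelines(f"{seq}\t{name}\n" for seq, name in FWD_BC)
    with open(path("r.txt"), "w") as fh:
        fh.writelines(f"{seq}\t{name}\n" for seq, name in REV_BC)
    with open(path("fwd.txt"), "w") as fh:
        fh.write(FWD.format(flist=path("f.txt")))
    with open(path("rev.txt"), "w") as fh:
        fh.write(REV.format(rlist=path("r.txt")))
    for slot, which in enumerate(("fwd_bc", "rev_bc")):
        with open(path(f"in{slot + 1}.fastq"), "w") as fh:
            for rid, fbc, rbc in PAIRS:
                seq = (fbc if slot == 0 else rbc) + "ACGT" * 5
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    stats = demultiplex(
        [path("in1.fastq"), path("in2.fastq")],
        [path("fwd.txt"), path("rev.txt")],
        os.path.join(work, "out", "matched_%f.pattern_name%.fastq"),
        os.path.join(work, "out", "unmatched.fastq"),
    )
    print(f"pairs in: {stats.records}   matched: {stats.matched}   "
          f"unmatched: {stats.unmatched}")
    for dest in sorted(stats.per_destination):
        print(f"  {os.path.basename(dest)}: {stats.per_destination[dest]}")

# The two concordant pairs land in their forward barcode's files (one file
# per input, suffixed _1/_2); the discordant pair fails the selected reverse
# barcode and both of its reads go to the unmatched files untouched.
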