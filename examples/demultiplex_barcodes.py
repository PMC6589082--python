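"""Demultiplex a small FASTQ file by 5' barcodes with one allowed edit.

Builds six reads over two barcodes, writes the canonical 4-line template
(the quality line is trimmed by the barcode match length via %b.length%),
runs the pipeline, and prints where every read went.
"""

import os
import tempfile

from fuzzysieve import demultiplex

TEMPLATE = """\
{{i}}
1 {{f required, trim, name = "b", edits = 1, pattern = f"{lists}"}}{{i}}
{{i}}
2 {{r trim, length = %b.length%}}{{i}}
"""

BARCODES = {"BC01": "ACGTACGT", "BC02": "TTGGCCAATTG"}

READS = [
    ("r1", BARCODES["BC01"] + "ACGTACGTACGTACGTACGT"),  # exact BC01
    ("r2", "AGGTACGT" + "CCCCCCCCCCCCCCCCCCCC"),        # BC01 with one edit
    ("r3", BARCODES["BC02"] + "ATATATATATATATATATAT"),  # exact BC02
    ("r4", "TTGGACAATTG" + "GGGGGGGGGGGGGGGGGGGG"),     # BC02 with one edit
    ("r5", "CACACACACACACACACACACACACACA"),             # no barcode
    ("r6", BARCODES["BC01"] + "TTTTTTTTTTTTTTTTTTTT"),  # exact BC01
]

with tempfile.TemporaryDirectory() as work:
    lists = os.path.join(work, "barcodes.txt")
    with open(lists, "w") as fh:
        for name, seq in BARCODES.items():
            fh.write(f"{seq}\t{name}\n")
    template = os.path.join(work, "template.txt")
    with open(template, "w") as fh:
        fh.write(TEMPLATE.format(lists=lists))
    fastq = os.path.join(work, "input.fastq")
    with open(fastq, "w") as fh:
        for rid, seq in READS:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    out = os.path.join(work, "out")
    stats = demultiplex(
        [fastq], [template],
        os.path.join(out, "matched_%b.pattern_name%.fastq"),
        os.path.join(out, "unmatched.fastq"),
    )

    print(f"records in: {stats.records}   matched: {stats.matched}   "
          f"unmatched: {stats.unmatched}")
    for path in sorted(stats.per_destination):
        print(f"  {os.path.basename(path)}: {stats.per_destination[path]} reads")

# Matched reads are trimmed (barcode removed from sequence, the same number
# of characters from the quality line) and routed to the file named after
# their barcode; the barcode-free read passes through unmodified.
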