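import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def write(tmp_path):
    """Write a text file under tmp_path and return its path."""

    def _write(name: str, content: str) -> str:
        p = tmp_path / name
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(content)
        return str(p)

    return _write


def fastq_record(rid: str, seq: str, qual: str | None = None) -> str:
    return f"@{rid}\n{seq}\n+\n{qual if qual is not None else 'I' * len(seq)}\n"


@pytest.fixture
def make_fastq(tmp_path):
    """Build a FASTQ file from (id, sequence) pairs."""

    def _make(name: str, reads) -> str:
        p = tmp_path / name
        p.write_text("".join(fastq_record(rid, seq) for rid, seq in reads))
        return str(p)

    return _make
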