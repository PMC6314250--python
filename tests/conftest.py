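"""Shared fixtures: tiny references, SAM text builders, synthetic sites."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from batchvar import ReferenceRepeat


@pytest.fixture
def small_reference() -> ReferenceRepeat:
    # 40 bp, hand-picked so every base appears
    return ReferenceRepeat(name="unit", sequence="ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")


@pytest.fixture
def fasta_file(tmp_path: Path):
    def _write(sequence: str, name: str = "unit", extra: str | None = None) -> Path:
        path = tmp_path / "ref.fa"
        text = f">{name}\n{sequence}\n"
        if extra is not None:
            text += f">second\n{extra}\n"
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def sam_file(tmp_path: Path):
    """Write a SAM text file over a named reference; reads are
    (name, flag, pos, cigar, seq, qual_string, extra_tags)."""

    def _write(reads, ref_name: str = "unit", ref_len: int = 40) -> Path:
        path = tmp_path / "reads.sam"
        lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{ref_name}\tLN:{ref_len}"]
        for name, flag, pos, cigar, seq, qual, *tags in reads:
            fields = [name, str(flag), ref_name, str(pos), "60", cigar, "*", "0", "0", seq, qual]
            fields.extend(tags)
            lines.append("\t".join(fields))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def q(char_quality: int, n: int) -> str:
    """Phred quality string of length n at a constant quality."""
    return chr(char_quality + 33) * n
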