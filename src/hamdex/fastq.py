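"""Minimal gzip-transparent FASTQ I/O (4-line records, Phred+33)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["open_text", "read_fastq", "FastqWriter", "phred_to_string", "string_to_phred"]

PHRED_OFFSET = 33


def open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality-string) records."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def phred_to_string(scores) -> str:
    return "".join(chr(int(q) + PHRED_OFFSET) for q in scores)


def string_to_phred(qual: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual]


class FastqWriter:
    """Append-style FASTQ writer; gzip output when the path ends in .gz."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh: TextIO = open_text(self.path, "wt")

    def write(self, title: str, seq: str, qual: str) -> None:
        self._fh.write(f"@{title}\n{seq}\n+\n{qual}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
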