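"""Small shared helpers."""

from __future__ import annotations

import gzip
from pathlib import Path


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    """Open a text file, transparently handling gzip by magic bytes."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | Path) -> str:
    """Return 'fastq' or 'fasta' from the first non-blank character."""
    with open_maybe_gzip(path, "rt") as handle:
        for line in handle:
            if line.strip():
                if line.startswith("@"):
                    return "fastq"
                if line.startswith(">"):
                    return "fasta"
                break
    raise ValueError(f"{path}: not recognizably FASTA or FASTQ")
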