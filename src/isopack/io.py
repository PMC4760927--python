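"""Sequence file I/O: FASTA/FASTQ, plain or gzipped, via Bio.SeqIO."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _guess_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def iter_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) from a FASTA/FASTQ file."""
    fmt = _guess_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def read_seqs(path: str | Path) -> list[str]:
    return [seq for _, seq in iter_seqs(path)]


def read_seq_dict(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rid, seq in iter_seqs(path):
        if rid in out:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        out[rid] = seq
    return out
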