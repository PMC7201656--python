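"""File I/O helpers: FASTQ/FASTA interchange and deterministic gzip.

Gzipped output is written with a zeroed mtime so that identical runs are
byte-identical.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .readprep import Read, ReadPair


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            return gzip.GzipFile(
                filename=str(path), mode="wb", mtime=0
            )  # deterministic
        return gzip.open(path, "rt")
    return open(path, mode)


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Load paired FASTQ files (R1/R2 in lockstep order)."""
    pairs = []
    with _open_text(r1_path, "rt") as f1, _open_text(r2_path, "rt") as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2):
            if id1.split()[0] != id2.split()[0]:
                raise ValueError(f"unpaired FASTQ records: {id1!r} vs {id2!r}")
            pairs.append(ReadPair(id1.split()[0], s1, s2, q1, q2))
    return pairs


def _write_lines(path, lines: Iterable[str]) -> None:
    data = "".join(lines).encode("ascii")
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.GzipFile(filename=str(path), mode="wb", mtime=0) as fh:
            fh.write(data)
    else:
        path.write_bytes(data)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    r1_lines, r2_lines = [], []
    for p in pairs:
        r1_lines.append(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
        r2_lines.append(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
    _write_lines(r1_path, r1_lines)
    _write_lines(r2_path, r2_lines)


def write_fastq_reads(reads: Iterable[Read], path) -> None:
    _write_lines(path, (f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n" for r in reads))


def read_fastq_reads(path) -> list[Read]:
    with _open_text(path, "rt") as fh:
        return [Read(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def read_fasta(path) -> dict[str, str]:
    with _open_text(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}\n")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width] + "\n")
    _write_lines(path, lines)
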