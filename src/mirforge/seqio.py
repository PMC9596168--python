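"""Readers and writers for the sequence formats the toolkit touches.

All sequences are normalized on input to uppercase DNA alphabet with U
mapped to T, so the rest of the toolkit can work on a single alphabet.
Qualities are parsed for FASTQ but never used by the algorithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

log = logging.getLogger("mirforge")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")
_RC = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_RC)[::-1]


@dataclass
class SeqRecord:
    """A named sequence, optionally with a Sanger quality string."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T. Raises on characters outside {A,C,G,T,U,N}."""
    out = seq.translate(_NORMALIZE)
    if not set(out) <= VALID_BASES:
        bad = sorted(set(out) - VALID_BASES)
        raise ValueError(f"invalid sequence characters: {bad}")
    return out


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, format: str | None = None) -> Iterator[SeqRecord]:
    """Stream records from a FASTA/FASTQ file in file order, normalized.

    Duplicate ids are de-duplicated by appending ``.2``, ``.3``, ... so ids
    are unique within a file. Malformed input raises ``ValueError``; an empty
    file yields an empty stream with a logged warning.
    """
    fmt = _infer_format(path, format)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format: {fmt}")
    seen: dict[str, int] = {}
    n = 0
    try:
        for rec in SeqIO.parse(str(path), fmt):
            n += 1
            name = rec.id
            if name in seen:
                seen[name] += 1
                name = f"{name}.{seen[rec.id]}"
            else:
                seen[name] = 1
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield SeqRecord(name, normalize_sequence(str(rec.seq)), qual)
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} record in {path} (record {n + 1}): {exc}")
    if n == 0:
        log.warning("no records parsed from %s", path)


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA; round-trips through :func:`read_sequences`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def candidate_header(cand_id: str, km: float, length: int, cc: int | None = None) -> str:
    """Machine-parsable FASTA header for a predicted mature miRNA.

    key=value pairs carry the expression (mean k-mer abundance), length and
    source connected component, e.g. ``candidate_1 km=12.0 len=21 cc=3``.
    """
    fields = [cand_id, f"km={km:.1f}", f"len={length}"]
    if cc is not None:
        fields.append(f"cc={cc}")
    return " ".join(fields)
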