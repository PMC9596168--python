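"""16-mer exclusion filter against other structured RNA classes.

sRNA-seq libraries contain fragments of rRNA, tRNA, snoRNA and similar
RNAs whose lengths overlap the miRNA range. Candidates matching a 16-mer
database built from such an "other RNA" reference collection (with known
mature-miRNA 16-mers subtracted so genuine miRNAs are never excluded) are
flagged and removed from the final catalog.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .components import Candidate
from .kmer_graph import canonical, count_kmers
from .seqio import SeqRecord, read_sequences


def build_filter_db(
    other_rna: Iterable[SeqRecord] | str | Path,
    mirna: Iterable[SeqRecord] | str | Path | None = None,
    filter_k: int = 16,
    min_count: int = 5,
) -> set[str]:
    """Canonical ``filter_k``-mers of the other-RNA collection, minus miRNA k-mers.

    k-mers with a collection-wide count below ``min_count`` are excluded;
    any k-mer present at least once in the mature-miRNA collection is
    subtracted. Accepts FASTA paths or record iterables.
    """
    if isinstance(other_rna, (str, Path)):
        other_rna = read_sequences(other_rna)
    kept = set(count_kmers(other_rna, filter_k, km_min=min_count).counts)
    if mirna is not None:
        if isinstance(mirna, (str, Path)):
            mirna = read_sequences(mirna)
        mir_kmers = set(count_kmers(mirna, filter_k, km_min=1).counts)
        kept -= mir_kmers
    return kept


def candidate_matches(sequence: str, kmer_set: set[str], filter_k: int = 16) -> bool:
    return any(
        canonical(sequence[i : i + filter_k]) in kmer_set
        for i in range(len(sequence) - filter_k + 1)
    )


def filter_candidates(
    candidates: list[Candidate], kmer_set: set[str], filter_k: int = 16
) -> tuple[list[Candidate], list[Candidate]]:
    """Split candidates into (kept, flagged_other_rna).

    A candidate is flagged iff at least one of its canonical
    ``filter_k``-mers is in the database. The empty set keeps everything.
    """
    kept: list[Candidate] = []
    flagged: list[Candidate] = []
    for cand in candidates:
        if kmer_set and candidate_matches(cand.sequence, kmer_set, filter_k):
            flagged.append(cand)
        else:
            kept.append(cand)
    return kept, flagged


def save_filter_db(kmer_set: set[str], path: str | Path, filter_k: int = 16, min_count: int = 5) -> None:
    """Plain-text serialization: a header line, then one k-mer per line."""
    with open(path, "w") as fh:
        fh.write(f"#mirforge-filter k={filter_k} min_count={min_count} n={len(kmer_set)}\n")
        for kmer in sorted(kmer_set):
            fh.write(kmer + "\n")


def load_filter_db(path: str | Path) -> tuple[set[str], int]:
    """Load a filter database; returns (k-mer set, k)."""
    kmers: set[str] = set()
    k = 16
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("k="):
                        k = int(tok[2:])
            elif line:
                kmers.add(line)
    return kmers, k
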