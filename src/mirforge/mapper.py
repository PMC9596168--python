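"""A-posteriori mapping of mature-miRNA candidates to a reference genome.

Because the candidate set is tiny compared to the raw reads, an exhaustive
edit-distance search is affordable: the genome is cut into nonoverlapping
200-bp windows, each window is indexed by all its overlapping forward
12-mers, and every candidate (both strands) is seeded against the index.
Each seeded window is aligned semi-globally (free ends on the window,
penalized ends on the candidate, Myers bit-vector via edlib); placements
within edit distance 2 are kept, deduplicated, ranked and truncated to the
best 100 locations. Putative precursors are then excised around each hit.

Windows carry a right extension of (one candidate length + allowed edits)
so placements straddling a window boundary are not lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import edlib

from .components import Candidate
from .config import RunConfig
from .seqio import SeqRecord, read_sequences, revcomp

log = logging.getLogger("mirforge")

#: right extension of each window, covering a max-length candidate crossing
#: the boundary (24 nt) so boundary-spanning alignments are recoverable
WINDOW_EXTENSION = 24


@dataclass
class GenomicHit:
    candidate_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # + or -
    edit_distance: int
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit span must be non-empty")


@dataclass
class Precursor:
    candidate_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_offset: int  # 0-based offset of the mature within the precursor


@dataclass
class WindowIndex:
    window_size: int
    seed_len: int
    chroms: dict[str, str] = field(default_factory=dict)
    # seed 12-mer -> list of (chrom, window index)
    seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def n_windows(self, chrom: str) -> int:
        n = len(self.chroms[chrom])
        return max(1, -(-n // self.window_size))

    def window_sequence(self, chrom: str, widx: int) -> tuple[str, int]:
        """Window plus right extension; returns (sequence, genomic offset)."""
        seq = self.chroms[chrom]
        start = widx * self.window_size
        end = min(len(seq), start + self.window_size + WINDOW_EXTENSION)
        return seq[start:end], start


def index_genome(
    genome: Iterable[SeqRecord] | str | Path, window: int = 200, seed_len: int = 12
) -> WindowIndex:
    """Index nonoverlapping windows of the genome by their forward seeds."""
    if isinstance(genome, (str, Path)):
        genome = read_sequences(genome)
    idx = WindowIndex(window_size=window, seed_len=seed_len)
    for rec in genome:
        seq = rec.sequence
        idx.chroms[rec.id] = seq
        for pos in range(0, max(1, len(seq) - seed_len + 1)):
            kmer = seq[pos : pos + seed_len]
            if len(kmer) < seed_len or "N" in kmer:
                continue
            widx = pos // window
            entry = (rec.id, widx)
            hits = idx.seeds.setdefault(kmer, [])
            if not hits or hits[-1] != entry:
                hits.append(entry)
    return idx


def _query_seeds(seq: str, seed_len: int) -> set[str]:
    return {seq[i : i + seed_len] for i in range(len(seq) - seed_len + 1)}


def map_candidate(
    candidate: Candidate | SeqRecord,
    index: WindowIndex,
    max_edit: int = 2,
    max_hits: int = 100,
    rescue_scan: bool = True,
) -> list[GenomicHit]:
    """Seed-and-extend a candidate against the genome index.

    Every overlapping seed of the candidate and of its reverse complement
    is queried; each seeded (window, strand) is aligned semi-globally and
    the best placement per window is kept if its edit distance is within
    ``max_edit``. Identical genomic spans are deduplicated, keeping the
    better distance; the hit list is sorted by (edit distance, coverage
    desc, chrom, start, strand) and truncated to ``max_hits``.

    Exact contiguous seeds cannot cover every placement within
    ``max_edit``: a single central substitution in a 21-mer already
    disrupts all of its 12-mers. With ``rescue_scan`` (default), a
    candidate whose seeded windows produce no hit is realigned against
    every window, preserving the exhaustive-search contract at the cost
    of a full scan for seedless candidates only.
    """
    cid = candidate.id
    seq = candidate.sequence
    queries = {"+": seq, "-": revcomp(seq)}
    windows: set[tuple[str, int, str]] = set()
    for strand, q in queries.items():
        for kmer in _query_seeds(q, index.seed_len):
            for chrom, widx in index.seeds.get(kmer, ()):
                windows.add((chrom, widx, strand))

    best = _align_windows(queries, sorted(windows), index, max_edit, cid)
    if not best and rescue_scan:
        all_windows = [
            (chrom, widx, strand)
            for chrom in sorted(index.chroms)
            for widx in range(index.n_windows(chrom))
            for strand in "+-"
        ]
        best = _align_windows(queries, all_windows, index, max_edit, cid)
    hits = sorted(
        best.values(),
        key=lambda h: (h.edit_distance, -h.coverage, h.chrom, h.start, h.strand),
    )
    return hits[:max_hits]


def _align_windows(queries, windows, index, max_edit, cid):
    best: dict[tuple[str, int, int, str], GenomicHit] = {}
    for chrom, widx, strand in windows:
        wseq, offset = index.window_sequence(chrom, widx)
        res = edlib.align(queries[strand], wseq, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] < 0:
            continue
        for loc_start, loc_end in res["locations"]:
            if loc_start is None:
                loc_start = 0
            start = offset + loc_start
            end = offset + loc_end + 1
            key = (chrom, start, end, strand)
            hit = GenomicHit(
                candidate_id=cid,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                edit_distance=res["editDistance"],
                coverage=min(1.0, (end - start) / len(queries[strand])),
            )
            prev = best.get(key)
            if prev is None or hit.edit_distance < prev.edit_distance:
                best[key] = hit
    return best


def excise_precursors(
    hit: GenomicHit,
    genome: dict[str, str] | WindowIndex,
    lengths: Iterable[int] = (110,),
    flank: int = 15,
) -> list[Precursor]:
    """Excise putative precursor windows around a hit, on the hit strand.

    For each length L two placements are emitted, putting the mature near
    either arm of the would-be hairpin: one anchored ``flank`` bases before
    the mature start, one ending ``flank`` bases after the mature end.
    Placements truncated by a contig edge are dropped (logged).
    """
    chroms = genome.chroms if isinstance(genome, WindowIndex) else genome
    seq = chroms[hit.chrom]
    out: list[Precursor] = []
    seen: set[tuple[int, int]] = set()
    for L in lengths:
        for p_start in ((hit.start - flank), (hit.end + flank - L)):
            p_end = p_start + L
            if p_start < 0 or p_end > len(seq):
                log.debug(
                    "precursor %s:%d-%d for %s clipped by contig edge; dropped",
                    hit.chrom, p_start, p_end, hit.candidate_id,
                )
                continue
            if (p_start, p_end) in seen:
                continue
            seen.add((p_start, p_end))
            prec_seq = seq[p_start:p_end]
            offset_plus = hit.start - p_start
            mature_len = hit.end - hit.start
            if hit.strand == "-":
                prec_seq = revcomp(prec_seq)
                offset = L - offset_plus - mature_len
            else:
                offset = offset_plus
            if offset < 0 or offset + mature_len > L:
                continue
            out.append(
                Precursor(
                    candidate_id=hit.candidate_id,
                    chrom=hit.chrom,
                    start=p_start,
                    end=p_end,
                    strand=hit.strand,
                    sequence=prec_seq,
                    mature_offset=offset,
                )
            )
    return out


def map_candidates(
    candidates: Iterable[Candidate],
    index: WindowIndex,
    cfg: RunConfig | None = None,
) -> dict[str, list[GenomicHit]]:
    cfg = cfg or RunConfig()
    return {
        cand.id: map_candidate(cand, index, cfg.map_max_edit, cfg.max_hits)
        for cand in candidates
    }


def hits_to_bed(hits: Iterable[GenomicHit], path: str | Path) -> None:
    """BED6: name = candidate id, score = edit distance."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.candidate_id}\t{h.edit_distance}\t{h.strand}\n"
            )
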