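"""sRNA-seq read simulator with ground truth, plus synthetic fixtures.

The simulator emulates a small-RNA library: 80% of reads are full-length
copies of mature miRNAs with per-molecule expression drawn log-uniformly
between 50 and 2000 (so low- and highly expressed miRNAs coexist), 10%
are random 18-30 nt fragments of decoy RNAs (the stand-in for rRNA/tRNA
and other structured RNAs) and 10% are random genomic fragments. Each
base is substituted independently with the configured error rate,
uniformly over the three alternatives. Output is deterministic for a
fixed seed.

``make_fixture`` generates the source material: random mature sequences
screened so that no two share a 15-mer and no pair is within edit
distance 3 (keeping the ground truth unambiguous for benchmarking),
decoy RNAs, and a random genome optionally carrying planted hairpin loci
whose arms embed chosen matures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recluster import edit_distance
from .seqio import SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALPHABET = "ACGT"

READ_LEN_RANGE = (18, 30)
DEPTH_RANGE = (50, 2000)
CLASS_FRACTIONS = {"mirna": 0.8, "rna_decoy": 0.1, "genomic_decoy": 0.1}


@dataclass
class SimTruth:
    """Ground truth: per-source class, sequence and realized read count."""

    table: pd.DataFrame  # columns: source_id, class, sequence, count

    def mirna_sequences(self) -> list[str]:
        sel = self.table[self.table["class"] == "mirna"]
        return list(sel["sequence"])


@dataclass
class SimulatedReads:
    reads: list[SeqRecord]
    truth: SimTruth
    #: per-read provenance: (source_id, class, start in source, strand='+')
    provenance: list[tuple[str, str, int]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_ALPHABET), size=length))


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        alts = [b for b in (b"A", b"C", b"G", b"T") if b != arr[pos]]
        arr[pos] = alts[rng.integers(3)]
    return arr.tobytes().decode()


def simulate(
    mirnas: list[SeqRecord],
    decoy_rna: list[SeqRecord],
    genome: list[SeqRecord],
    n_reads: int = 200_000,
    error_rate: float = 0.01,
    rng_seed: int = 42,
    depth_lo: float = DEPTH_RANGE[0],
    depth_hi: float = DEPTH_RANGE[1],
) -> SimulatedReads:
    """Simulate a small-RNA library; returns reads, truth and provenance.

    miRNA reads copy the full mature sequence; decoy reads are uniform
    substrings of length 18-30. The per-miRNA read counts are a
    multinomial draw over log-uniform weights, so they sum exactly to the
    miRNA read budget.
    """
    if not mirnas:
        raise ValueError("miRNA source set must be nonempty")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    if genome and max(len(g.sequence) for g in genome) < 30:
        raise ValueError("genome contigs must be at least 30 nt")
    rng = np.random.default_rng(rng_seed)
    n_mir = int(round(CLASS_FRACTIONS["mirna"] * n_reads))
    n_rna = int(round(CLASS_FRACTIONS["rna_decoy"] * n_reads))
    n_gen = n_reads - n_mir - n_rna

    weights = np.exp(rng.uniform(np.log(depth_lo), np.log(depth_hi), size=len(mirnas)))
    counts = rng.multinomial(n_mir, weights / weights.sum())

    reads: list[SeqRecord] = []
    provenance: list[tuple[str, str, int]] = []
    truth_rows: list[dict] = []
    rid = 0

    for mir, count in zip(mirnas, counts):
        truth_rows.append(
            {"source_id": mir.id, "class": "mirna", "sequence": mir.sequence, "count": int(count)}
        )
        for _ in range(count):
            rid += 1
            seq = _apply_errors(mir.sequence, error_rate, rng)
            reads.append(
                SeqRecord(
                    f"read_{rid} source={mir.id} class=mirna start=0", seq, "I" * len(seq)
                )
            )
            provenance.append((mir.id, "mirna", 0))

    def _fragment_reads(sources: list[SeqRecord], n: int, cls: str) -> None:
        nonlocal rid
        decoy_counts: dict[str, int] = {s.id: 0 for s in sources}
        for _ in range(n):
            rid += 1
            src = sources[rng.integers(len(sources))]
            length = int(rng.integers(READ_LEN_RANGE[0], READ_LEN_RANGE[1] + 1))
            length = min(length, len(src.sequence))
            start = int(rng.integers(0, len(src.sequence) - length + 1))
            seq = _apply_errors(src.sequence[start : start + length], error_rate, rng)
            reads.append(
                SeqRecord(
                    f"read_{rid} source={src.id} class={cls} start={start}",
                    seq,
                    "I" * len(seq),
                )
            )
            provenance.append((src.id, cls, start))
            decoy_counts[src.id] += 1
        for src in sources:
            truth_rows.append(
                {
                    "source_id": src.id,
                    "class": cls,
                    "sequence": src.sequence,
                    "count": decoy_counts[src.id],
                }
            )

    if decoy_rna and n_rna:
        _fragment_reads(decoy_rna, n_rna, "rna_decoy")
    elif n_rna:
        n_gen += n_rna
    if genome and n_gen:
        _fragment_reads(genome, n_gen, "genomic_decoy")

    truth = SimTruth(pd.DataFrame(truth_rows, columns=["source_id", "class", "sequence", "count"]))
    return SimulatedReads(reads=reads, truth=truth, provenance=provenance)


def mismatch_fraction(sim: SimulatedReads, sources: dict[str, str]) -> tuple[float, int]:
    """Empirical per-base substitution rate, by comparing each read to its
    known source span. Returns (fraction, bases compared)."""
    mism = 0
    total = 0
    for rec, (src_id, _cls, start) in zip(sim.reads, sim.provenance):
        ref = sources[src_id][start : start + len(rec.sequence)]
        total += len(ref)
        mism += sum(a != b for a, b in zip(rec.sequence, ref))
    return (mism / total if total else 0.0), total


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    mirnas: list[SeqRecord]
    decoys: list[SeqRecord]
    genome: list[SeqRecord]
    #: (mature id, chrom, genomic start of precursor, mature offset in arm)
    planted: list[tuple[str, str, int, int]] = field(default_factory=list)


def _shares_15mer(a: str, b: str, k: int = 15) -> bool:
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    kmers_a |= {revcomp(a)[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers_a for i in range(len(b) - k + 1))


def make_hairpin_precursor(
    mature: str,
    rng: np.random.Generator,
    total_len: int = 110,
    loop_len: int = 8,
    mature_offset: int = 15,
) -> tuple[str, int]:
    """Perfect-stem hairpin embedding the mature on the 5' arm.

    Returns (precursor sequence, mature offset). The arm is the mature
    plus random padding; the 3' arm is its reverse complement. The mature
    sits ``mature_offset`` bases into the arm, matching the flank used by
    precursor excision so a mapped mature excises exactly this hairpin.
    """
    arm_len = (total_len - loop_len) // 2
    pad_total = arm_len - len(mature)
    if pad_total < 0:
        raise ValueError("precursor too short for the mature sequence")
    pad5 = min(mature_offset, pad_total)
    arm = _random_seq(rng, pad5) + mature + _random_seq(rng, pad_total - pad5)
    loop = "".join(rng.choice(["A", "C"], size=loop_len))  # unpairable loop
    prec = arm + loop + revcomp(arm)
    prec = prec + _random_seq(rng, total_len - len(prec))
    return prec, pad5


def make_fixture(
    n_mirnas: int = 100,
    n_decoys: int = 30,
    genome_len: int = 20_000,
    n_hairpins: int = 0,
    rng_seed: int = 42,
    max_tries: int = 200,
) -> Fixture:
    """Generate matures, decoy RNAs and a genome (optionally with planted
    hairpin loci) for simulation and mapper/hairpin testing."""
    rng = np.random.default_rng(rng_seed)
    mirnas: list[SeqRecord] = []
    for i in range(n_mirnas):
        for attempt in range(max_tries):
            length = int(rng.integers(18, 25))
            cand = _random_seq(rng, length)
            ok = all(
                not _shares_15mer(cand, m.sequence) and edit_distance(cand, m.sequence) > 3
                for m in mirnas
            )
            if ok:
                mirnas.append(SeqRecord(f"mir_{i + 1}", cand))
                break
        else:
            raise RuntimeError("could not screen a novel mature sequence; relax n or retries")

    decoys = [
        SeqRecord(f"decoy_{j + 1}", _random_seq(rng, int(rng.integers(100, 301))))
        for j in range(n_decoys)
    ]

    genome_seq = _random_seq(rng, genome_len)
    planted: list[tuple[str, str, int, int]] = []
    if n_hairpins:
        chosen = list(range(min(n_hairpins, n_mirnas)))
        slot = genome_len // (len(chosen) + 1)
        parts = []
        cursor = 0
        for idx, mi in enumerate(chosen):
            prec, off = make_hairpin_precursor(mirnas[mi].sequence, rng)
            pos = (idx + 1) * slot
            parts.append(genome_seq[cursor:pos])
            planted.append((mirnas[mi].id, "chr1", pos, off))
            parts.append(prec)
            cursor = pos
        parts.append(genome_seq[cursor:])
        genome_seq = "".join(parts)
        # re-anchor planted coordinates after insertion shifts
        shift = 0
        fixed = []
        for (mid, chrom, pos, off), mi in zip(planted, chosen):
            fixed.append((mid, chrom, pos + shift, off))
            shift += 110
        planted = fixed
    genome = [SeqRecord("chr1", genome_seq)]
    return Fixture(mirnas=mirnas, decoys=decoys, genome=genome, planted=planted)
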