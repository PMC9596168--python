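"""End-to-end orchestration of the discovery and validation stages.

``run_core`` is the reference-free discovery pipeline: k-mer counting
with an abundance floor, unipath-graph compaction, tip removal,
expression-ratio arc pruning (followed by a second tip pass),
artifact-component removal, per-component reassembly and classification,
two-stage reclustering, and the optional other-RNA 16-mer exclusion
filter. ``run_to_reference`` chains the genome mapper and the hairpin
validator over the discovered candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import clean, components, hairpin, kmer_graph, mapper, recluster, rna_filter, seqio
from .config import RunConfig

log = logging.getLogger("mirforge")


@dataclass
class CoreResult:
    candidates: list[components.Candidate]
    isomirs: list[tuple[components.Candidate, str]]
    longer: list[components.AssembledComponent]
    others: list[components.AssembledComponent]
    flagged_other_rna: list[components.Candidate]
    graph: kmer_graph.UnipathGraph
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_core(
    reads: Iterable[seqio.SeqRecord] | str | Path,
    cfg: RunConfig | None = None,
    filter_db: set[str] | None = None,
) -> CoreResult:
    """Run the discovery pipeline on reads (records or a FASTA/FASTQ path)."""
    cfg = cfg or RunConfig()
    if isinstance(reads, (str, Path)):
        reads = seqio.read_sequences(reads)
    counts: dict[str, int] = {}

    table = kmer_graph.count_kmers(reads, cfg.k, cfg.km_min)
    counts["kmers"] = len(table)
    graph = kmer_graph.build_unipath_graph(table)
    counts["unipaths"] = len(graph.unipaths)
    counts["arcs"] = len(graph.arcs)

    graph = clean.remove_tips(graph, cfg.tip_km_max, cfg.tip_iterations)
    counts["unipaths_after_tips"] = len(graph.unipaths)
    graph = clean.prune_expression_arcs(graph, cfg.fold_threshold)
    counts["arcs_after_pruning"] = len(graph.arcs)
    graph = clean.remove_tips(graph, cfg.tip_km_max, cfg.tip_iterations)
    graph = clean.remove_artifact_components(graph, cfg.tip_km_max)
    counts["unipaths_after_cleaning"] = len(graph.unipaths)

    cands, longer, others = components.classify_components(graph, cfg)
    counts["components_candidates"] = len(cands)
    counts["components_longer"] = len(longer)

    rec = recluster.recluster(cands, cfg.overlap_k, cfg.recluster_max_edit)
    counts["candidates_after_recluster"] = len(rec.final_candidates)

    if filter_db:
        kept, flagged = rna_filter.filter_candidates(
            rec.final_candidates, filter_db, cfg.filter_k
        )
    else:
        kept, flagged = rec.final_candidates, []
    counts["candidates_final"] = len(kept)

    for stage, value in counts.items():
        log.info("stage %s: %d", stage, value)
    return CoreResult(
        candidates=kept,
        isomirs=rec.isomirs + rec.stage1_members,
        longer=longer,
        others=others,
        flagged_other_rna=flagged,
        graph=graph,
        stage_counts=counts,
    )


def write_core_outputs(result: CoreResult, outdir: str | Path) -> None:
    """FASTA catalogs, the expression table and the final graph as GFA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(
        [
            seqio.SeqRecord(
                seqio.candidate_header(c.id, c.expression, len(c), c.source_cc), c.sequence
            )
            for c in result.candidates
        ],
        outdir / "candidates.fa",
    )
    seqio.write_fasta(
        [
            seqio.SeqRecord(f"{iso.id} representative={rep}", iso.sequence)
            for iso, rep in result.isomirs
        ],
        outdir / "isomirs.fa",
    )
    seqio.write_fasta(
        [
            seqio.SeqRecord(f"longer_{i + 1} km={c.km:.1f} len={c.length}", c.sequence)
            for i, c in enumerate(result.longer)
        ],
        outdir / "longer.fa",
    )
    seqio.write_fasta(
        [
            seqio.SeqRecord(
                seqio.candidate_header(c.id, c.expression, len(c), c.source_cc), c.sequence
            )
            for c in result.flagged_other_rna
        ],
        outdir / "other_srnas.fa",
    )
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("id\tsequence\tlength\tkm\tcc\tn_isomirs\n")
        for c in result.candidates:
            fh.write(
                f"{c.id}\t{c.sequence}\t{len(c)}\t{c.expression:.2f}\t{c.source_cc}\t{len(c.members)}\n"
            )
    kmer_graph.write_gfa(result.graph, outdir / "graph.gfa")
    with open(outdir / "stage_counts.tsv", "w") as fh:
        for stage, value in result.stage_counts.items():
            fh.write(f"{stage}\t{value}\n")


@dataclass
class ReferenceResult:
    hits: dict[str, list[mapper.GenomicHit]]
    validations: dict[str, hairpin.CandidateValidation]

    @property
    def validated_ids(self) -> list[str]:
        return [cid for cid, v in self.validations.items() if v.validated]


def run_to_reference(
    candidates: list[components.Candidate],
    genome: Iterable[seqio.SeqRecord] | str | Path,
    cfg: RunConfig | None = None,
) -> ReferenceResult:
    """Map candidates to the genome and validate hairpin precursors."""
    cfg = cfg or RunConfig()
    index = mapper.index_genome(genome, cfg.window_size, cfg.seed_len)
    hits = mapper.map_candidates(candidates, index, cfg)
    validations = hairpin.validate_candidates(candidates, hits, index, cfg)
    n_ok = sum(v.validated for v in validations.values())
    log.info("validated %d of %d candidates", n_ok, len(candidates))
    return ReferenceResult(hits=hits, validations=validations)


def write_reference_outputs(result: ReferenceResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_hits = [h for hits in result.hits.values() for h in hits]
    mapper.hits_to_bed(all_hits, outdir / "hits.bed")
    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("candidate\tchrom\tstart\tend\tstrand\tedit_distance\tcoverage\n")
        for h in all_hits:
            fh.write(
                f"{h.candidate_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.edit_distance}\t{h.coverage:.3f}\n"
            )
    precs = []
    with open(outdir / "validation.tsv", "w") as fh:
        fh.write("candidate\tvalidated\tn_hits\tn_precursors\tmfe\tstructure\n")
        for cid, v in result.validations.items():
            mfe = f"{v.best_fold.mfe:.2f}" if v.best_fold else ""
            db = v.best_fold.dot_bracket if v.best_fold else ""
            fh.write(f"{cid}\t{int(v.validated)}\t{v.n_hits}\t{v.n_precursors}\t{mfe}\t{db}\n")
            if v.best_precursor is not None:
                p = v.best_precursor
                precs.append(
                    seqio.SeqRecord(
                        f"{cid} {p.chrom}:{p.start + 1}-{p.end}({p.strand}) mature_offset={p.mature_offset}",
                        p.sequence,
                    )
                )
    seqio.write_fasta(precs, outdir / "precursors.fa")
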