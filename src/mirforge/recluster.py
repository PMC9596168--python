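"""Two-stage reclustering of miRNA candidates.

The graph-cleaning passes can split one mature miRNA (and its isomiRs or
error variants) across several components. Stage 1 reconnects candidates
that share an exact 15-mer (in either orientation, since candidates are
strand-ambiguous); stage 2 merges the stage-1 representatives within
Levenshtein distance 2. In each cluster the most expressed candidate is
the representative; all other members are reported as putative isomiRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx

from .components import Candidate
from .seqio import revcomp


def edit_distance(a: str, b: str, strand_aware: bool = True) -> int:
    """Global Levenshtein distance, minimized over orientation by default."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    if strand_aware:
        d = min(d, edlib.align(a, revcomp(b), mode="NW", task="distance")["editDistance"])
    return d


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_by_shared_kmer(candidates: list[Candidate], overlap_k: int = 15) -> list[list[Candidate]]:
    """Connect candidates sharing >= 1 exact ``overlap_k``-mer; return clusters.

    Each candidate's forward k-mers are compared against both the forward
    and reverse-complement k-mers of the others (inverted-index
    implementation). Clusters are the connected components of the overlap
    graph, in deterministic order.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    index: dict[str, list[int]] = {}
    for i, cand in enumerate(candidates):
        kmers = _kmer_set(cand.sequence, overlap_k) | _kmer_set(revcomp(cand.sequence), overlap_k)
        for kmer in kmers:
            index.setdefault(kmer, []).append(i)
    for hits in index.values():
        for a, b in zip(hits, hits[1:]):
            g.add_edge(a, b)
    clusters = [sorted(cc) for cc in nx.connected_components(g)]
    clusters.sort(key=lambda cc: cc[0])
    return [[candidates[i] for i in cc] for cc in clusters]


def select_representative(cluster: list[Candidate]) -> tuple[Candidate, list[Candidate]]:
    """Most expressed candidate wins; ties go to the smaller sequence."""
    if not cluster:
        raise ValueError("empty cluster")
    rep = min(cluster, key=lambda c: (-c.expression, c.sequence))
    members = [c for c in cluster if c is not rep]
    return rep, members


@dataclass
class ReclusterResult:
    final_candidates: list[Candidate]
    isomirs: list[tuple[Candidate, str]] = field(default_factory=list)  # (isomiR, representative id)
    stage1_members: list[tuple[Candidate, str]] = field(default_factory=list)


def cluster_by_edit_distance(
    representatives: list[Candidate], max_edit: int = 2
) -> tuple[list[Candidate], list[tuple[Candidate, str]]]:
    """Merge representatives within edit distance ``max_edit`` (either strand).

    Per connected component the most expressed candidate becomes the final
    candidate; the rest are putative isomiRs annotated with its id.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(representatives)))
    for i in range(len(representatives)):
        for j in range(i + 1, len(representatives)):
            if edit_distance(representatives[i].sequence, representatives[j].sequence) <= max_edit:
                g.add_edge(i, j)
    finals: list[Candidate] = []
    isomirs: list[tuple[Candidate, str]] = []
    clusters = [sorted(cc) for cc in nx.connected_components(g)]
    clusters.sort(key=lambda cc: cc[0])
    for cc in clusters:
        rep, members = select_representative([representatives[i] for i in cc])
        rep.members = rep.members + [m.sequence for m in members]
        finals.append(rep)
        isomirs.extend((m, rep.id) for m in members)
    return finals, isomirs


def recluster(candidates: list[Candidate], overlap_k: int = 15, max_edit: int = 2) -> ReclusterResult:
    """Run both stages; no candidate is lost (final + isomiR + member = input)."""
    reps: list[Candidate] = []
    stage1_members: list[tuple[Candidate, str]] = []
    for cluster in cluster_by_shared_kmer(candidates, overlap_k):
        rep, members = select_representative(cluster)
        rep.members = rep.members + [m.sequence for m in members]
        stage1_members.extend((m, rep.id) for m in members)
        reps.append(rep)
    finals, isomirs = cluster_by_edit_distance(reps, max_edit)
    return ReclusterResult(final_candidates=finals, isomirs=isomirs, stage1_members=stage1_members)
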