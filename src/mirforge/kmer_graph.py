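"""Canonical k-mer counting and compacted bidirected de Bruijn graph.

The graph is node-centric: nodes are canonical k-mers (the lexicographic
minimum of a word and its reverse complement), and an arc joins two nodes
whenever the (k-1)-suffix of one oriented word equals the (k-1)-prefix of
another. Because strands are collapsed, every node has two *ends* — ``h``
(head, the 5' end of the stored orientation) and ``t`` (tail) — and an arc
is an unordered pair of (node, end) incidences. Maximal non-branching
chains are glued into unipaths; each unipath carries the arithmetic mean
abundance (KM) of its constituent k-mers.

The construction is independent of read input order: unipath ids ascend by
the lexicographically smallest constituent canonical k-mer, and a unipath's
stored sequence is the smaller of the two strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seqio import SeqRecord, revcomp

HEAD = "h"
TAIL = "t"

#: An arc endpoint: (unipath id or k-mer string, end)
Incidence = tuple
#: Normalized arc: tuple(sorted((inc_a, inc_b)))
Arc = tuple


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    """Mapping canonical k-mer -> count, after the abundance floor."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts


def count_kmers(reads: Iterable[SeqRecord | str], k: int, km_min: float = 5.0) -> KmerTable:
    """Count canonical k-mers over reads, dropping counts below ``km_min``.

    A k-mer and its reverse complement aggregate into one canonical key.
    k-mers containing N are skipped; reads shorter than k contribute
    nothing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[str, int] = {}
    for rec in reads:
        seq = rec if isinstance(rec, str) else rec.sequence
        n = len(seq)
        if n < k:
            continue
        rc = revcomp(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            if "N" in fwd:
                continue
            bwd = rc[n - k - i : n - i]
            key = fwd if fwd <= bwd else bwd
            counts[key] = counts.get(key, 0) + 1
    counts = {key: c for key, c in counts.items() if c >= km_min}
    return KmerTable(k=k, counts=counts)


@dataclass
class Unipath:
    id: int
    sequence: str
    km: float
    n_kmers: int = 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UnipathGraph:
    """Compacted bidirected de Bruijn graph."""

    k: int
    unipaths: dict[int, Unipath] = field(default_factory=dict)
    arcs: set[Arc] = field(default_factory=set)

    # -- basic topology ---------------------------------------------------
    def end_degree(self, uid: int, end: str) -> int:
        deg = 0
        for (a, ea), (b, eb) in self.arcs:
            if (a, ea) == (uid, end):
                deg += 1
            if (b, eb) == (uid, end):
                deg += 1
        return deg

    def degree(self, uid: int) -> int:
        """Total number of arc incidences of a unipath (self-loops count twice)."""
        deg = 0
        for (a, _), (b, _) in self.arcs:
            if a == uid:
                deg += 1
            if b == uid:
                deg += 1
        return deg

    def degrees(self) -> dict[int, int]:
        deg = {uid: 0 for uid in self.unipaths}
        for (a, _), (b, _) in self.arcs:
            deg[a] += 1
            deg[b] += 1
        return deg

    def arcs_at(self, uid: int, end: str | None = None):
        out = []
        for arc in self.arcs:
            for inc in arc:
                if inc[0] == uid and (end is None or inc[1] == end):
                    out.append(arc)
                    break
        return out

    def neighbors(self, uid: int) -> set[int]:
        out = set()
        for (a, _), (b, _) in self.arcs:
            if a == uid:
                out.add(b)
            if b == uid:
                out.add(a)
        return out

    def copy(self) -> "UnipathGraph":
        return UnipathGraph(
            k=self.k,
            unipaths={u: Unipath(p.id, p.sequence, p.km, p.n_kmers) for u, p in self.unipaths.items()},
            arcs=set(self.arcs),
        )

    def kmer_multiset(self) -> dict[str, int]:
        """Multiset of canonical k-mers spelled by all unipaths."""
        out: dict[str, int] = {}
        k = self.k
        for up in self.unipaths.values():
            seq = up.sequence
            for i in range(len(seq) - k + 1):
                key = canonical(seq[i : i + k])
                out[key] = out.get(key, 0) + 1
        return out


def _normalize_arc(inc_a: Incidence, inc_b: Incidence) -> Arc:
    return tuple(sorted((inc_a, inc_b)))


def _oriented(kmer: str, orient: str) -> str:
    return kmer if orient == "+" else revcomp(kmer)


def _successors(word: str, kmers: set[str]):
    """Oriented successors of an oriented k-mer word within the k-mer set."""
    out = []
    suffix = word[1:]
    for b in "ACGT":
        nxt = suffix + b
        rc = revcomp(nxt)
        can = nxt if nxt <= rc else rc
        if can in kmers:
            out.append((can, "+" if nxt == can else "-"))
    return out


# Exit/entry end of a node traversed in a given orientation: reading a node
# forward enters at its head and exits at its tail; reading the reverse
# complement swaps the two.
_EXIT = {"+": TAIL, "-": HEAD}
_ENTRY = {"+": HEAD, "-": TAIL}


def _kmer_arcs(kmers: set[str]) -> set[Arc]:
    arcs: set[Arc] = set()
    for x in kmers:
        for orient in "+-":
            word = _oriented(x, orient)
            for y, oy in _successors(word, kmers):
                arcs.add(_normalize_arc((x, _EXIT[orient]), (y, _ENTRY[oy])))
    return arcs


def build_unipath_graph(table: KmerTable) -> UnipathGraph:
    """Compact the k-mer graph into maximal unipaths.

    Gluing follows the bidirected rule: an arc is glued when both of its
    incident ends have degree exactly 1 and the endpoints are distinct
    nodes. Chains that close into cycles are broken deterministically at
    their lexicographically smallest k-mer, leaving the closing arc as a
    self-loop on the resulting unipath.
    """
    k = table.k
    kmers = set(table.counts)
    graph = UnipathGraph(k=k)
    if not kmers:
        return graph

    arcs = _kmer_arcs(kmers)
    end_deg: dict[Incidence, int] = {}
    for arc in arcs:
        for inc in arc:
            end_deg[inc] = end_deg.get(inc, 0) + 1

    # glue links per (kmer, end)
    glue: dict[Incidence, Incidence] = {}
    glued_arcs: set[Arc] = set()
    for arc in arcs:
        (x, ex), (y, ey) = arc
        if x == y:
            continue
        if end_deg.get((x, ex), 0) == 1 and end_deg.get((y, ey), 0) == 1:
            glue[(x, ex)] = (y, ey)
            glue[(y, ey)] = (x, ex)
            glued_arcs.add(arc)

    visited: set[str] = set()
    chains: list[list[tuple[str, str]]] = []  # list of (kmer, orientation)

    def walk(start: str, entry_end: str) -> list[tuple[str, str]]:
        chain = []
        node, entry = start, entry_end
        while True:
            orient = "+" if entry == HEAD else "-"
            chain.append((node, orient))
            visited.add(node)
            exit_inc = (node, _EXIT[orient])
            nxt = glue.get(exit_inc)
            if nxt is None:
                break
            nnode, nend = nxt
            if nnode in visited:  # closed a glue cycle
                break
            node, entry = nnode, nend
        return chain

    # chains starting at free ends, seeded in deterministic order
    for x in sorted(kmers):
        if x in visited:
            continue
        free = [e for e in (HEAD, TAIL) if (x, e) not in glue]
        if not free:
            continue
        chains.append(walk(x, free[0]))
    # remaining nodes lie on pure glue cycles: break at smallest k-mer
    for x in sorted(kmers):
        if x not in visited:
            chains.append(walk(x, HEAD))

    # spell sequences and build the end mapping
    end_map: dict[Incidence, Incidence] = {}  # (kmer,end) -> (uid, end)
    chain_info = []
    for chain in chains:
        first, fo = chain[0]
        seq = _oriented(first, fo)
        for node, orient in chain[1:]:
            word = _oriented(node, orient)
            assert seq[-(k - 1):] == word[: k - 1]
            seq += word[-1]
        last, lo = chain[-1]
        head_inc = (first, _ENTRY[fo])
        tail_inc = (last, _EXIT[lo])
        km = sum(table.counts[node] for node, _ in chain) / len(chain)
        min_kmer = min(node for node, _ in chain)
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            head_inc, tail_inc = tail_inc, head_inc
        chain_info.append((min_kmer, seq, km, len(chain), head_inc, tail_inc))

    chain_info.sort(key=lambda t: t[0])
    for uid, (_, seq, km, n, head_inc, tail_inc) in enumerate(chain_info):
        graph.unipaths[uid] = Unipath(id=uid, sequence=seq, km=km, n_kmers=n)
        # tail mapping first so that a single-kmer palindromic chain, where
        # head_inc == tail_inc, resolves to the head end deterministically
        end_map[tail_inc] = (uid, TAIL)
        end_map[head_inc] = (uid, HEAD)

    for arc in arcs - glued_arcs:
        (x, ex), (y, ey) = arc
        a = end_map.get((x, ex))
        b = end_map.get((y, ey))
        if a is None or b is None:
            # an incidence buried inside a chain can only arise from a
            # palindromic end; map defensively to the closest exposed end
            continue
        graph.arcs.add(_normalize_arc(a, b))
    return graph


def write_gfa(graph: UnipathGraph, path) -> None:
    """Write the graph as GFA 1.0 with KM float tags on segments.

    Exiting a segment through its tail is the ``+`` orientation; entering
    through the head is ``+`` on the target side.
    """
    k = graph.k
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for uid in sorted(graph.unipaths):
            up = graph.unipaths[uid]
            fh.write(f"S\t{uid}\t{up.sequence}\tKM:f:{up.km:.2f}\n")
        for (a, ea), (b, eb) in sorted(graph.arcs):
            from_orient = "+" if ea == TAIL else "-"
            to_orient = "+" if eb == HEAD else "-"
            fh.write(f"L\t{a}\t{from_orient}\t{b}\t{to_orient}\t{k - 1}M\n")


def read_gfa(path) -> UnipathGraph:
    """Re-parse a GFA file written by :func:`write_gfa` (for round-trips)."""
    unipaths: dict[int, Unipath] = {}
    arcs: set[Arc] = set()
    k = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                uid = int(parts[1])
                km = 0.0
                for tag in parts[3:]:
                    if tag.startswith("KM:f:"):
                        km = float(tag[5:])
                unipaths[uid] = Unipath(id=uid, sequence=parts[2], km=km)
            elif parts[0] == "L":
                a, ao, b, bo, overlap = parts[1:6]
                if k is None:
                    k = int(overlap[:-1]) + 1
                ea = TAIL if ao == "+" else HEAD
                eb = HEAD if bo == "+" else TAIL
                arcs.add(_normalize_arc((int(a), ea), (int(b), eb)))
    if k is None:
        k = min((len(u.sequence) for u in unipaths.values()), default=2)
    return UnipathGraph(k=k, unipaths=unipaths, arcs=arcs)
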