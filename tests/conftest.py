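"""Shared fixtures and independent oracle implementations.

The oracles deliberately use different algorithms from the package
(oriented-digraph walking instead of end-based gluing, quadratic DP
instead of bit-vector alignment, exhaustive structure enumeration instead
of the folding DP) so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mirforge.seqio import revcomp


# ---------------------------------------------------------------------------
# unipath compaction oracle: walk maximal non-branching paths of the
# oriented (doubled) de Bruijn digraph, then collapse strand duplicates
# ---------------------------------------------------------------------------

def oracle_unipaths(kmers: set[str], k: int) -> list[str]:
    """Unipath sequences (canonical strand) of the k-mer set.

    Works on the doubled digraph (both strands as separate words). An edge
    u->v is glued iff outdeg(u) == 1, indeg(v) == 1, and the words are not
    strand twins of each other; unipaths are the resulting chains. Each
    chain appears once per strand, so results are collapsed to canonical
    sequences.
    """
    nodes = set()
    for km in kmers:
        nodes.add(km)
        nodes.add(revcomp(km))

    def succs(w):
        return [w[1:] + b for b in "ACGT" if (w[1:] + b) in nodes]

    def preds(w):
        return [b + w[:-1] for b in "ACGT" if (b + w[:-1]) in nodes]

    glue_next = {}
    glue_prev = {}
    for u in nodes:
        out = succs(u)
        if len(out) == 1:
            v = out[0]
            if len(preds(v)) == 1 and min(u, revcomp(u)) != min(v, revcomp(v)):
                glue_next[u] = v
                glue_prev[v] = u

    sequences = []
    visited = set()
    starts = sorted(w for w in nodes if w not in glue_prev)
    for start in starts:
        seq = start
        visited.add(start)
        cur = start
        while cur in glue_next:
            cur = glue_next[cur]
            visited.add(cur)
            seq += cur[-1]
        sequences.append(seq)
    # pure glue cycles: break at the smallest member
    for w in sorted(nodes - visited):
        if w in visited:
            continue
        seq = w
        visited.add(w)
        cur = w
        while glue_next.get(cur) not in (None, w):
            cur = glue_next[cur]
            visited.add(cur)
            seq += cur[-1]
        sequences.append(seq)
    return sorted({min(s, revcomp(s)) for s in sequences})


# ---------------------------------------------------------------------------
# quadratic Levenshtein DP
# ---------------------------------------------------------------------------

def dp_edit_distance(a: str, b: str) -> int:
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def dp_infix_distance(query: str, ref: str) -> int:
    """Semi-global: full query aligned, free ends on the reference."""
    m, n = len(query), len(ref)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (query[i - 1] != ref[j - 1]),
            )
        prev = cur
    return min(prev)


# ---------------------------------------------------------------------------
# exhaustive secondary-structure enumeration (for short sequences)
# ---------------------------------------------------------------------------

_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every non-crossing pair set over the RNA string."""
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + min_loop + 1, n)
        if seq[i] + seq[j] in _PAIRS
    ]

    def compatible(p, q):
        i, j = p
        x, y = q
        if len({i, j, x, y}) < 4:
            return False
        return not (i < x < j < y or x < i < y < j)

    def rec(chosen, rest):
        yield chosen
        for idx, p in enumerate(rest):
            if all(compatible(p, c) for c in chosen):
                yield from rec(chosen + [p], rest[idx + 1 :])

    yield from rec([], candidates)


def oracle_fold_energy(seq: str) -> float:
    from mirforge.hairpin import structure_energy, _to_rna

    rna = _to_rna(seq)
    return min(structure_energy(rna, s) for s in enumerate_structures(rna))


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_reads(rng, n_seqs=4, seq_len=60, copies=6, read_len=20):
    """Reads drawn from a few random source sequences, above the floor."""
    reads = []
    for _ in range(n_seqs):
        src = "".join(rng.choice(list("ACGT"), size=seq_len))
        for start in range(0, seq_len - read_len + 1, 7):
            reads.extend([src[start : start + read_len]] * copies)
    return reads
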