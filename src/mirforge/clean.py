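"""Graph-editing passes that strip sequencing-error structure.

Three passes, applied to the compacted de Bruijn graph:

1. iterative tip removal — dead-end unipaths (total degree <= 1) with low
   mean abundance are artifacts of sequencing errors; highly expressed
   isolated nodes are kept because a fully sequenced mature miRNA collapses
   to exactly one isolated unipath;
2. expression-ratio arc pruning — a mature miRNA has uniform coverage
   along its sequence, so an arc joining unipaths whose KM values differ by
   more than 3-fold joins different molecules (or errors) and is deleted;
3. artifact-component removal — connected components made of lowly
   expressed nodes containing a branching node of degree 3-5 match the
   topologies produced by error tangles and are dropped wholesale.

Each pass only deletes; node and arc counts are non-increasing.
"""

from __future__ import annotations

import logging

from .kmer_graph import UnipathGraph

log = logging.getLogger("mirforge")


def remove_tips(graph: UnipathGraph, km_max: float = 5.0, iterations: int = 3) -> UnipathGraph:
    """Iteratively delete low-abundance dead ends (mark-then-sweep).

    Per iteration every unipath with total degree <= 1 and km <= km_max is
    marked, then all marked unipaths and their incident arcs are deleted
    simultaneously, so the result does not depend on traversal order.
    Isolated unipaths (degree 0) with km > km_max survive by the same
    condition.
    """
    g = graph.copy()
    for it in range(iterations):
        deg = g.degrees()
        doomed = {uid for uid, d in deg.items() if d <= 1 and g.unipaths[uid].km <= km_max}
        if not doomed:
            break
        for uid in doomed:
            del g.unipaths[uid]
        g.arcs = {arc for arc in g.arcs if arc[0][0] not in doomed and arc[1][0] not in doomed}
        log.debug("tip removal iteration %d: deleted %d unipaths", it + 1, len(doomed))
    return g


def prune_expression_arcs(graph: UnipathGraph, fold: float = 3.0) -> UnipathGraph:
    """Delete arcs whose endpoint KM values differ by more than ``fold``.

    Symmetric in arc direction: uses max(km_i, km_j) / min(km_i, km_j).
    Nodes are untouched; callers re-run :func:`remove_tips` afterwards.
    """
    g = graph.copy()
    kept = set()
    for arc in g.arcs:
        (a, _), (b, _) = arc
        km_a = g.unipaths[a].km
        km_b = g.unipaths[b].km
        ratio = max(km_a, km_b) / min(km_a, km_b)
        if ratio <= fold:
            kept.add(arc)
    n_removed = len(g.arcs) - len(kept)
    if n_removed:
        log.debug("expression-arc pruning: deleted %d arcs", n_removed)
    g.arcs = kept
    return g


def _undirected_components(graph: UnipathGraph) -> list[set[int]]:
    parent = {uid: uid for uid in graph.unipaths}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, _), (b, _) in graph.arcs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for uid in graph.unipaths:
        groups.setdefault(find(uid), set()).add(uid)
    return list(groups.values())


def remove_artifact_components(graph: UnipathGraph, km_max: float = 5.0) -> UnipathGraph:
    """Drop whole components that look like error tangles.

    A component is removed iff it contains at least one node of degree
    3, 4 or 5 and every node in it has km <= km_max. Purely linear
    low-abundance components are left to the tip pass.
    """
    g = graph.copy()
    deg = g.degrees()
    doomed: set[int] = set()
    n_cc = 0
    n_removed = 0
    for cc in _undirected_components(g):
        n_cc += 1
        has_branch = any(deg[uid] in (3, 4, 5) for uid in cc)
        all_low = all(g.unipaths[uid].km <= km_max for uid in cc)
        if has_branch and all_low:
            doomed |= cc
            n_removed += 1
    for uid in doomed:
        del g.unipaths[uid]
    g.arcs = {arc for arc in g.arcs if arc[0][0] not in doomed and arc[1][0] not in doomed}
    if n_cc:
        log.debug(
            "artifact-component removal: deleted %d of %d components (%.1f%%)",
            n_removed, n_cc, 100.0 * n_removed / n_cc,
        )
    return g
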