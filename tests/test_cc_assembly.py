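import numpy as np

from conftest import random_reads
from mirforge.components import (
    ComponentClass,
    classify_components,
    connected_components,
    reassemble_component,
)
from mirforge.config import RunConfig
from mirforge.kmer_graph import HEAD, TAIL, Unipath, UnipathGraph, build_unipath_graph, count_kmers
from mirforge.seqio import revcomp


def graph_from_reads(reads, k=14, km_min=5):
    return build_unipath_graph(count_kmers(reads, k, km_min))


def abstract_graph(n, arcs, kms=None, seq_len=14):
    g = UnipathGraph(k=14)
    for i in range(n):
        g.unipaths[i] = Unipath(i, "A" * seq_len, (kms or [10] * n)[i])
    for a, b in arcs:
        g.arcs.add(tuple(sorted(((a, TAIL), (b, HEAD)))))
    return g


class TestConnectedComponents:
    def test_empty_graph(self):
        assert connected_components(UnipathGraph(k=14)) == []

    def test_disjoint_unipaths(self):
        g = abstract_graph(2, [])
        assert connected_components(g) == [[0], [1]]

    def test_matches_transitive_closure_oracle(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            n = 15
            arcs = [(int(r.integers(n)), int(r.integers(n))) for _ in range(10)]
            g = abstract_graph(n, [(a, b) for a, b in arcs if a != b])
            # oracle: boolean reachability closure
            adj = np.eye(n, dtype=bool)
            for a, b in arcs:
                adj[a, b] = adj[b, a] = True
            for _ in range(n):
                adj = adj @ adj
            oracle = sorted(
                sorted(np.nonzero(adj[i])[0].tolist())
                for i in range(n)
            )
            oracle = [cc for i, cc in enumerate(sorted({tuple(c) for c in oracle}))]
            got = {tuple(cc) for cc in connected_components(g)}
            assert got == {tuple(c) for c in oracle}


class TestReassembly:
    def test_two_unipath_linear_concatenation(self):
        # terminal branch, then one fork arm deleted (as cleaning would do):
        # a 19-nt and a 14-nt unipath joined by one arc spell 20 nt
        src = "ACGTTGCAAGCTTACGGATC"  # 20 nt
        other = src[:-1] + "G"
        g = graph_from_reads([src] * 5 + [other] * 5)
        # remove the fork arm belonging to `other`
        from mirforge.seqio import revcomp as rc
        doomed = next(
            u for u, up in g.unipaths.items()
            if len(up.sequence) == 14
            and up.sequence not in (src[6:], rc(src[6:]))
        )
        del g.unipaths[doomed]
        g.arcs = {a for a in g.arcs if a[0][0] != doomed and a[1][0] != doomed}
        cc = connected_components(g)[0]
        assert len(cc) == 2
        comp = reassemble_component(g, cc, 0)
        assert comp.component_class is ComponentClass.CANDIDATE
        assert comp.length == 19 + 14 - 13 == 20
        assert comp.sequence in (src, rc(src))

    def test_length_identity_on_linear_components(self, rng):
        reads = random_reads(rng, n_seqs=4, seq_len=55, copies=6, read_len=20)
        g = graph_from_reads(reads)
        k = g.k
        for cc_id, cc in enumerate(connected_components(g)):
            comp = reassemble_component(g, cc, cc_id)
            if comp.sequence is None:
                continue
            expected = sum(len(g.unipaths[u]) for u in cc) - (len(cc) - 1) * (k - 1)
            assert comp.length == expected

    def test_reassembled_sequence_spells_component_kmers(self, rng):
        reads = random_reads(rng, n_seqs=3, seq_len=50, copies=6, read_len=20)
        g = graph_from_reads(reads)
        k = g.k
        for cc_id, cc in enumerate(connected_components(g)):
            comp = reassemble_component(g, cc, cc_id)
            if comp.sequence is None:
                continue
            spelled = {
                min(comp.sequence[i : i + k], revcomp(comp.sequence[i : i + k]))
                for i in range(comp.length - k + 1)
            }
            member_kmers = set()
            for u in cc:
                s = g.unipaths[u].sequence
                member_kmers |= {
                    min(s[i : i + k], revcomp(s[i : i + k]))
                    for i in range(len(s) - k + 1)
                }
            assert spelled == member_kmers

    def test_cycle_classified_circular(self):
        g = abstract_graph(3, [(0, 1), (1, 2), (2, 0)])
        comp = reassemble_component(g, [0, 1, 2])
        assert comp.component_class is ComponentClass.CIRCULAR
        assert comp.sequence is None

    def test_degree3_node_classified_branching(self):
        g = abstract_graph(4, [(0, 1), (0, 2), (0, 3)])
        comp = reassemble_component(g, [0, 1, 2, 3])
        assert comp.component_class is ComponentClass.BRANCHING

    def test_km_is_length_weighted_mean(self):
        seq = "ACGTTGCAAGCTTACGGATC"
        other = seq[:-1] + "G"
        g = graph_from_reads([seq] * 10 + [other] * 5)
        # take the component containing the shared unipath
        ccs = connected_components(g)
        comp = reassemble_component(g, max(ccs, key=len), 0)
        if comp.sequence is not None:
            total = sum(len(g.unipaths[u]) for u in comp.members)
            expected = sum(len(g.unipaths[u]) * g.unipaths[u].km for u in comp.members) / total
            assert abs(comp.km - expected) < 1e-9


class TestClassification:
    def test_isolated_expressed_candidate(self):
        g = abstract_graph(1, [], kms=[60], seq_len=21)
        cands, longer, others = classify_components(g, RunConfig())
        assert len(cands) == 1 and not longer and not others
        assert cands[0].expression == 60

    def test_isolated_moderate_km_discarded(self):
        g = abstract_graph(1, [], kms=[30], seq_len=21)
        cands, longer, others = classify_components(g, RunConfig())
        assert not cands
        assert others[0].component_class is ComponentClass.DISCARDED_ISOLATED

    def test_linear_multinode_longer(self):
        seq = "ACGTTGCAAGCTTACGGATCACGGTTCAGA"  # 30 nt
        other = seq[:-1] + "C"
        g = graph_from_reads([seq] * 8 + [other] * 8)
        # delete the fork arm that spells `other`, leaving a linear 2-node CC
        doomed = next(
            u for u, up in g.unipaths.items()
            if len(up.sequence) == 14
            and seq[16:] not in (up.sequence, revcomp(up.sequence))
        )
        del g.unipaths[doomed]
        g.arcs = {a for a in g.arcs if a[0][0] != doomed and a[1][0] != doomed}
        cands, longer, others = classify_components(g, RunConfig())
        assert any(c.length == 30 for c in longer)

    def test_every_component_has_exactly_one_class(self, rng):
        reads = random_reads(rng, n_seqs=6, seq_len=60, copies=6, read_len=20)
        g = graph_from_reads(reads)
        cands, longer, others = classify_components(g, RunConfig())
        assert len(cands) + len(longer) + len(others) == len(connected_components(g))
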