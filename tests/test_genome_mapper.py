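import numpy as np
import pytest

from conftest import dp_infix_distance
from mirforge.components import Candidate
from mirforge.mapper import (
    GenomicHit,
    excise_precursors,
    index_genome,
    map_candidate,
)
from mirforge.seqio import SeqRecord, revcomp


def random_genome(rng, n=1000, name="chr1"):
    return SeqRecord(name, "".join(rng.choice(list("ACGT"), size=n)))


@pytest.fixture
def genome(rng):
    return random_genome(rng)


@pytest.fixture
def planted(rng):
    """Genome with a 21-nt candidate planted at position 57."""
    g = random_genome(rng, 1000)
    mature = "".join(rng.choice(list("ACGT"), size=21))
    seq = g.sequence[:57] + mature + g.sequence[57 + 21 :]
    return SeqRecord("chr1", seq), mature


class TestIndex:
    def test_window_counts(self, rng):
        idx = index_genome([random_genome(rng, 400)])
        assert idx.n_windows("chr1") == 2
        idx = index_genome([random_genome(rng, 412)])
        assert idx.n_windows("chr1") == 3

    def test_seed_positions_per_window(self, rng):
        idx = index_genome([random_genome(rng, 200)])
        total = sum(len(v) for v in idx.seeds.values())
        assert total == 200 - 12 + 1  # 189

    def test_short_chromosome_single_window(self, rng):
        idx = index_genome([random_genome(rng, 10)])
        assert idx.n_windows("chr1") == 1
        assert not idx.seeds  # too short for any 12-mer


class TestMapping:
    def test_exact_planted_hit(self, planted):
        genome, mature = planted
        idx = index_genome([genome])
        hits = map_candidate(Candidate("c1", mature, 10.0), idx)
        assert hits
        best = hits[0]
        assert (best.start, best.end) == (57, 78)
        assert best.edit_distance == 0
        assert best.coverage == 1.0
        assert best.strand == "+"

    def test_reverse_strand_hit(self, planted):
        genome, mature = planted
        idx = index_genome([genome])
        hits = map_candidate(Candidate("c1", revcomp(mature), 10.0), idx)
        assert hits and hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (57, 78)

    def test_single_substitution_found(self, planted, rng):
        genome, mature = planted
        mutated = list(mature)
        mutated[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[10]]
        mutated = "".join(mutated)
        idx = index_genome([genome])
        hits = map_candidate(Candidate("c1", mutated, 10.0), idx)
        assert hits and hits[0].edit_distance == 1
        assert hits[0].start == 57 and hits[0].end == 78

    def test_boundary_spanning_hit_recovered(self, rng):
        g = random_genome(rng, 600)
        mature = "".join(rng.choice(list("ACGT"), size=22))
        seq = g.sequence[:190] + mature + g.sequence[190 + 22 :]
        idx = index_genome([SeqRecord("chr1", seq)])
        hits = map_candidate(Candidate("c1", mature, 10.0), idx)
        assert any(h.start == 190 and h.edit_distance == 0 for h in hits)

    def test_reported_distance_confirmed_by_full_dp(self, rng):
        g = random_genome(rng, 2000)
        idx = index_genome([g])
        for trial in range(10):
            pos = int(rng.integers(0, 2000 - 22))
            query = list(g.sequence[pos : pos + 22])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(len(query)))
                query[p] = "ACGT"[int(rng.integers(4))]
            query = "".join(query)
            for hit in map_candidate(Candidate("q", query, 1.0), idx):
                lo = max(0, hit.start - 2)
                hi = min(2000, hit.end + 2)
                q = query if hit.strand == "+" else revcomp(query)
                assert dp_infix_distance(q, g.sequence[lo:hi]) == hit.edit_distance

    def test_hit_cap_and_ordering(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=40))
        g = SeqRecord("chr1", unit * 150)  # 150 identical placements
        idx = index_genome([g])
        query = unit[5:27]
        hits = map_candidate(Candidate("q", query, 1.0), idx, max_hits=100)
        assert len(hits) == 100
        keys = [(h.edit_distance, -h.coverage, h.chrom, h.start, h.strand) for h in hits]
        assert keys == sorted(keys)

    def test_no_hit_returns_empty(self, genome):
        idx = index_genome([genome])
        assert map_candidate(Candidate("q", "A" * 22, 1.0), idx) == []


class TestPlantedRecovery:
    def test_single_edit_always_recovered(self, rng):
        # pigeonhole: 18 nt with 1 edit still contains an intact 12-mer seed
        g = random_genome(rng, 3000)
        idx = index_genome([g])
        for trial in range(20):
            pos = int(rng.integers(0, 3000 - 24))
            length = int(rng.integers(18, 25))
            query = list(g.sequence[pos : pos + length])
            edit_pos = int(rng.integers(length))
            query[edit_pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[edit_pos]]
            hits = map_candidate(Candidate("q", "".join(query), 1.0), idx)
            assert any(
                h.edit_distance <= 1 and abs(h.start - pos) <= 2 for h in hits
            ), f"planted hit lost at trial {trial}"


class TestPrecursorExcision:
    def hit(self, start=500, end=522, strand="+"):
        return GenomicHit("c1", "chr1", start, end, strand, 0)

    def test_animal_two_precursors(self, genome):
        precs = excise_precursors(self.hit(), {"chr1": genome.sequence}, [110])
        assert len(precs) == 2
        assert all(len(p.sequence) == 110 for p in precs)

    def test_plant_ten_precursors(self, genome):
        precs = excise_precursors(
            self.hit(), {"chr1": genome.sequence}, [110, 150, 200, 250, 300]
        )
        assert len(precs) == 10

    def test_near_edge_placement_dropped(self, genome):
        # hit at 50: the 3'-anchored placement would start at 72+15-110 < 0
        precs = excise_precursors(self.hit(50, 72), {"chr1": genome.sequence}, [110])
        assert len(precs) == 1
        # very close to the edge, both placements are clipped away
        assert excise_precursors(self.hit(5, 27), {"chr1": genome.sequence}, [110]) == []

    def test_mature_contained_and_offset_correct(self, genome):
        for strand in "+-":
            for p in excise_precursors(
                self.hit(strand=strand), {"chr1": genome.sequence}, [110]
            ):
                mature = genome.sequence[500:522]
                if strand == "-":
                    mature = revcomp(mature)
                assert (
                    p.sequence[p.mature_offset : p.mature_offset + 22] == mature
                )
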