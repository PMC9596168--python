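from collections import Counter

import numpy as np
import pytest

from conftest import oracle_fold_energy
from mirforge.components import Candidate
from mirforge.config import RunConfig
from mirforge.hairpin import (
    FoldResult,
    annotate_structure,
    fold,
    fold_rnafold,
    mature_on_arm,
    parse_pairs,
    validate_candidates,
    validate_precursor,
)
from mirforge.mapper import index_genome, map_candidates
from mirforge.simulate import make_fixture, make_hairpin_precursor


class TestFold:
    def test_canonical_stem_loop(self):
        fr = fold("GGGGAAAACCCC")
        assert fr.dot_bracket == "((((....))))"
        assert fr.mfe < 0

    def test_unpairable_sequence_all_dots(self):
        fr = fold("AAAAAAAAAAAA")
        assert fr.dot_bracket == "." * 12
        assert fr.mfe == 0.0

    def test_deterministic(self):
        seq = "GCAUUCGAGGCUAAGCGU"
        assert fold(seq) == fold(seq)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGX")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 17))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        fr = fold(seq)
        assert fr.mfe == pytest.approx(oracle_fold_energy(seq), abs=1e-6)
        # the traced structure realizes the DP energy
        from mirforge.hairpin import structure_energy

        assert structure_energy(seq, parse_pairs(fr.dot_bracket)) == pytest.approx(
            fr.mfe, abs=1e-6
        )

    def test_rnafold_engine_agrees_on_strong_hairpin(self):
        # both engines should see a single clean stem-loop here
        rng = np.random.default_rng(0)
        prec, _ = make_hairpin_precursor("ACGUUGCAAGCUUACGGAUCA".replace("U", "T"), rng)
        for engine in ("builtin", "rnafold"):
            fr = fold(prec, engine)
            ann = annotate_structure(fr.dot_bracket)
            assert ann.n_hairpin_loops == 1
            assert fr.mfe < -25


class TestAnnotation:
    def test_canonical_stem_loop(self):
        ann = annotate_structure("((((....))))")
        assert ann.n_hairpin_loops == 1
        assert ann.n_segments == 1
        assert ann.n_bulges == ann.n_internal_loops == ann.n_multiloops == 0
        assert ann.n_dangling_ends == 0

    def test_multiloop_fixture(self):
        ann = annotate_structure("..((((..((....))..((....))..)))).. ".strip())
        assert ann.n_multiloops == 1
        assert ann.n_hairpin_loops == 2
        assert ann.n_dangling_ends == 2
        assert ann.n_segments == 1

    def test_bulge_fixture(self):
        ann = annotate_structure("((.((....))))")
        assert ann.n_bulges == 1
        assert ann.n_hairpin_loops == 1
        assert ann.n_internal_loops == 0

    def test_internal_loop_fixture(self):
        ann = annotate_structure("((..((....))..))")
        assert ann.n_internal_loops == 1
        assert ann.n_bulges == 0

    def test_external_loop_between_stems(self):
        ann = annotate_structure("((....))..((....))")
        assert ann.n_external_loops == 1
        assert ann.n_segments == 2
        assert ann.n_dangling_ends == 0

    def test_pseudoknot_flagged_via_layers(self):
        ann = annotate_structure("((..[[..))..]]")
        assert ann.has_pseudoknot

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError):
            annotate_structure("((...)")

    @pytest.mark.parametrize(
        "db",
        [
            "((((....))))",
            "..((((..((....))..((....))..))))..",
            "((.((....))))",
            "((..((....))..))",
            "((....))..((....))",
            "....",
            ".((((((...((((((.......))))))...))))))...",
        ],
    )
    def test_position_conservation(self, db):
        ann = annotate_structure(db)
        assert len(ann.position_classes) == len(db)
        counts = Counter(ann.position_classes)
        assert counts["paired"] == sum(db.count(c) for c in "()")
        assert sum(counts.values()) == len(db)


class TestValidation:
    def good_annotation(self):
        return annotate_structure("(((((((((((....)))))))))))")

    def test_synthetic_precursor_passes(self):
        rng = np.random.default_rng(42)
        prec, _ = make_hairpin_precursor("ACGTTGCAAGCTTACGGATCA", rng)
        fr = fold(prec)
        ann = annotate_structure(fr.dot_bracket)
        report = validate_precursor(ann, fr, RunConfig())
        assert report.passed, report.reasons

    def test_two_hairpins_fail(self):
        ann = annotate_structure("((....))((....))")
        fr = FoldResult("((....))((....))", -40.0)
        report = validate_precursor(ann, fr, RunConfig(), engine="builtin")
        assert not report.passed
        assert "multi-hairpin" in report.reasons

    def test_weak_energy_fails(self):
        ann = self.good_annotation()
        report = validate_precursor(ann, FoldResult(str(ann), -5.0), RunConfig())
        assert "energy" in report.reasons

    def test_reason_codes_accumulate(self):
        ann = annotate_structure("..((..((....))..((....))..))..[[..]]")
        report = validate_precursor(ann, FoldResult("", -5.0), RunConfig())
        assert {"energy", "multi-hairpin", "multiloop"} <= set(report.reasons)

    def test_threshold_monotonicity(self):
        # loosening the energy window never un-passes a structure
        rng = np.random.default_rng(3)
        prec, _ = make_hairpin_precursor("ACGTTGCAAGCTTACGGATCA", rng)
        fr = fold(prec)
        ann = annotate_structure(fr.dot_bracket)
        tight = RunConfig(mfe_lo=25.0, mfe_hi=200.0)
        loose = RunConfig(mfe_lo=1.0, mfe_hi=1000.0)
        if validate_precursor(ann, fr, tight).passed:
            assert validate_precursor(ann, fr, loose).passed

    def test_mature_on_arm_check(self):
        ann = annotate_structure("((((((((((....))))))))))")
        # hairpin loop at positions 10..13
        assert mature_on_arm(ann, 0, 8)
        assert mature_on_arm(ann, 14, 8)
        assert not mature_on_arm(ann, 6, 8)  # spans the loop


class TestValidateCandidates:
    def test_planted_hairpins_validated_background_not(self):
        fx = make_fixture(n_mirnas=8, n_decoys=2, genome_len=6000, n_hairpins=4, rng_seed=9)
        cands = [Candidate(m.id, m.sequence, 100.0) for m in fx.mirnas]
        idx = index_genome([fx.genome[0]])
        hits = map_candidates(cands, idx)
        out = validate_candidates(cands, hits, idx, RunConfig())
        planted = {p[0] for p in fx.planted}
        for cid, v in out.items():
            if cid in planted:
                assert v.validated, f"{cid} should validate"
            else:
                assert not v.validated, f"{cid} has no genomic locus"

    def test_candidate_without_hits_not_validated(self):
        fx = make_fixture(n_mirnas=2, n_decoys=1, genome_len=3000, rng_seed=4)
        cands = [Candidate(m.id, m.sequence, 50.0) for m in fx.mirnas]
        idx = index_genome([fx.genome[0]])
        out = validate_candidates(cands, {c.id: [] for c in cands}, idx, RunConfig())
        assert not any(v.validated for v in out.values())
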