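"""Validate candidates a posteriori against a reference genome.

Plants hairpin precursors (perfect stems embedding known matures) in a
random genome, maps each candidate at edit distance <= 2, excises putative
precursors around every hit, folds them, and checks the canonical
single-hairpin structure. Planted loci validate; matures without a
genomic hairpin do not.
"""

from mirforge import Candidate, make_fixture, run_to_reference

fixture = make_fixture(
    n_mirnas=8, n_decoys=2, genome_len=6000, n_hairpins=4, rng_seed=9
)
candidates = [Candidate(m.id, m.sequence, 100.0) for m in fixture.mirnas]
result = run_to_reference(candidates, fixture.genome)

planted = {p[0] for p in fixture.planted}
for cid, v in result.validations.items():
    mark = "planted" if cid in planted else "background"
    mfe = f"MFE={v.best_fold.mfe:.1f}" if v.best_fold else "no valid precursor"
    print(f"{cid:8s} [{mark:10s}] hits={v.n_hits} validated={v.validated} {mfe}")
print("\nA candidate validates when at least one excised precursor folds")
print("into a single-hairpin stem-loop with the mature on one arm.")
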