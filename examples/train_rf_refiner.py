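"""Train the random-forest refiner and score candidates with it.

Every 15-mer of a reference mature collection becomes a positive example;
an equal number of random 15-mers become negatives. Each 15-mer is
described by 19 features (composition, skew, CpG density, entropy and
complexity measures, plus reference 6/7/8-mer frequencies); a candidate
is kept when the mean predicted miRNA probability of its overlapping
15-mers exceeds 0.5.
"""

from mirforge import Candidate, make_fixture
from mirforge.features import build_training_set, classify_candidates, train_rf

fixture = make_fixture(n_mirnas=120, n_decoys=5, genome_len=2000, rng_seed=3)
positives, negatives = build_training_set(fixture.mirnas, rng_seed=3)
model = train_rf(positives, negatives, n_trees=200, rng_seed=3)

print(f"training 15-mers: {len(positives)} positive / {len(negatives)} random")
print(f"hold-out accuracy={model.accuracy:.3f} precision={model.precision:.3f} "
      f"recall={model.recall:.3f}")
top = sorted(model.feature_importances.items(), key=lambda kv: -kv[1])[:5]
print("most informative features:", ", ".join(f"{k}={v:.3f}" for k, v in top))

candidates = [Candidate(m.id, m.sequence, 10.0) for m in fixture.mirnas[:10]]
kept, rejected = classify_candidates(candidates, model)
print(f"refiner keeps {len(kept)}/{len(candidates)} held-out mature candidates")
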