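# mirforge

Reference-free discovery of mature microRNAs (miRNAs) from small-RNA
sequencing (sRNA-seq) reads.

Most miRNA discovery tools map reads to a reference genome and look for
hairpin precursors, which fails or degrades for the many species without a
high-quality assembly. `mirforge` instead encodes the entire read set in a
compacted bidirected de Bruijn graph (k = 14) and reads mature miRNA
candidates — 18–24 nt sequences with uniform read support — directly out of
the graph. Companion tools map candidates to a genome *a posteriori* and
validate hairpin precursors, refine predictions with a random-forest
sequence classifier, simulate sRNA-seq libraries with ground truth, and
score predictions against a truth set.

## Method

**Core discovery.** Canonical k-mers (a word collapsed with its reverse
complement) are counted over the reads and those with abundance below
KM<sub>min</sub> = 5 are discarded. The de Bruijn graph over the surviving
k-mers — arcs join words overlapping by k−1 bases — is compacted into
maximal unipaths, each carrying the arithmetic mean abundance (KM) of its
k-mers. Three cleaning passes remove sequencing-error structure:

1. *tip removal* (×3 iterations): dead-end unipaths (degree ≤ 1) with
   KM ≤ 5 are deleted; highly expressed isolated nodes are kept, because a
   fully sequenced mature miRNA collapses to exactly one isolated unipath;
2. *expression-ratio arc pruning*: an arc whose endpoint KMs differ by more
   than 3-fold (max(KM<sub>i</sub>, KM<sub>j</sub>)/min > 3) joins different
   molecules and is deleted, after which tips are removed again;
3. *artifact components*: connected components made entirely of low-KM
   nodes and containing a branching node of degree 3–5 are dropped.

Each surviving linear component is reassembled (length
L = Σ len<sub>i</sub> − (n−1)(k−1)) and classified: 18–24 nt → candidate
(isolated single-node components additionally need KM > 50), > 24 nt →
longer expressed sequence, circular/branching → set aside. Candidates are
then reclustered in two stages — exact shared 15-mers, then Levenshtein
distance ≤ 2 on cluster representatives — with the most expressed member
representing each cluster and the rest reported as putative isomiRs.
Finally, candidates matching a 16-mer database built from an "other RNA"
reference collection (minus known-miRNA 16-mers) are flagged and removed.

**Genome validation.** Each candidate is aligned to the genome in
nonoverlapping 200-bp windows indexed by 12-mers, both strands, keeping
placements with edit distance ≤ 2 (Myers bit-vector via edlib; at most 100
best hits). Putative precursors (110 nt for animals; 110–300 nt for plants)
are excised around each hit, folded, and accepted when the structure is a
single-hairpin stem-loop without pseudoknots, multiloops or external loops,
with < 5 bulges, < 3 dangling ends, < 10 internal loops, the minimum free
energy inside the configured window, and the mature on one stem arm.

**Random-forest refiner.** Candidates are decomposed into 15-mers; each is
described by 19 features (GC content and skew, CpG density, Wootton–
Federhen and Shannon entropy, Markov conditional entropies cm1–cm3,
Trifonov ct3–ct6 and linguistic cl3–cl6 complexities, and reference
6/7/8-mer frequencies). A forest trained on reference-mature versus random
15-mers (75/25 split) scores candidates by mean probability.

**Benchmarking.** The simulator emits 80% full-length mature reads
(per-molecule depth log-uniform in [50, 2000]), 10% decoy-RNA fragments and
10% genomic fragments (18–30 nt), with independent per-base substitutions.
Predictions are scored as precision = TP/(TP+FP), recall = TP/(TP+FN) and
their harmonic mean (F-score), with edit-distance-2 matching by default.

## Worked example

```bash
python examples/discover_from_reads.py
```

simulates 20,000 reads from 20 planted matures plus background and runs the
core pipeline:

```
kmers                            3749
unipaths                         569
arcs                             319
unipaths_after_tips              400
arcs_after_pruning               171
unipaths_after_cleaning          385
components_candidates            23
components_longer                47
candidates_after_recluster       20
candidates_final                 20

20 candidates; recall=1.00 precision=1.00
  candidate_1: GAAAATCAACCCTTGTCA km=146
```

3,749 above-floor k-mers compact into 569 unipaths; cleaning strips
error-derived tips and arcs; exactly the 20 planted matures survive as
candidates, each reported with its expression (`km`, mean k-mer abundance).
`examples/validate_against_genome.py`, `examples/simulate_and_benchmark.py`
and `examples/train_rf_refiner.py` demonstrate the genome validator, the
benchmark loop and the refiner the same way.

The same functionality is exposed as a CLI:

```bash
mirforge discover reads.fastq -o out/         # candidates, isomiRs, GFA, ...
mirforge map-reference out/candidates.fa genome.fa
mirforge build-filter other_rna.fa --mirna mature.fa
mirforge simulate matures.fa --decoys rfam.fa --genome genome.fa
mirforge evaluate out/candidates.fa truth.fa
mirforge rf-train mature.fa && mirforge rf-classify out/candidates.fa rf_model.joblib
mirforge fixture --n-mirnas 100
```

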