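# Methods

This note records the model behind each stage, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## The graph model

Reads are reduced to canonical k-mers: a k-mer and its reverse complement
are one object, keyed by the lexicographically smaller string, so the
pipeline is strand-agnostic end to end. The de Bruijn graph is node-centric
and bidirected: each node has a *head* and a *tail* end, and an arc is an
unordered pair of (node, end) incidences recording which oriented ends
overlap by k−1 bases. Compaction glues an arc when both incident ends have
degree exactly 1 and the endpoints are distinct nodes; chains that close
into cycles are broken at their lexicographically smallest k-mer, leaving
the closing arc as a self-loop (such components classify as circular
downstream). Unipath ids ascend by smallest constituent k-mer and the
stored strand is the lexicographically smaller one, so the graph is
invariant under read-order permutation — a property the tests assert.

Parameters: `k = 14` (smaller than the 18–24 nt mature length, trading
specificity for error tolerance and cluster sensitivity), `km_min = 5`
(k-mer abundance floor; k-mers seen fewer than 5 times are treated as
noise). The abundance floor is applied after strand canonicalization:
counts aggregate over both strands first, then the floor cuts. k-mers
containing N are skipped during counting; N is retained in read sequences.

## Graph cleaning

- **Tips** (degree ≤ 1, KM ≤ `tip_km_max` = 5) are deleted
  mark-then-sweep so one iteration's outcome cannot depend on traversal
  order; the pass runs `tip_iterations` = 3 times. Isolated nodes with
  KM > 5 survive the rule by construction — an expressed mature miRNA *is*
  an isolated unipath, so deleting expressed isolated nodes would delete
  the signal.
- **Arc pruning** removes arcs with max(KM)/min(KM) > `fold_threshold` = 3
  (a mature miRNA has uniform coverage along its sequence, so a 3-fold
  jump marks a boundary between different molecules or between signal and
  error). The ratio is symmetric, so the pass cannot depend on arc
  direction. Tips are removed again afterwards, which clears the
  newly isolated low-abundance debris.
- **Artifact components** are deleted when every node has KM ≤ 5 and some
  node has degree 3–5. The rule is deliberately conjunctive and
  conservative: purely linear low-KM components are left to the tip pass,
  and any component containing one expressed node is kept.

## Component classification

Linear components (all degrees ≤ 2, ≥ 1 endpoint) are reassembled by
walking the path and concatenating oriented sequences with (k−1)-overlaps;
the identity L = Σ len_i − (n−1)(k−1) is asserted in tests. The
reassembled KM is the length-weighted mean of member KMs so that short
branch stubs cannot dominate. Components where the walk fails
(inconsistent orientations, internal loops) are classified branching
defensively rather than crashing. Isolated single-node components must
clear `isolated_km_min` = 50 to become candidates; isolated 18–24 nt nodes
with 5 < KM ≤ 50 are discarded. This bar is what keeps error-derived
bubbles out of the catalog: a substitution seen recurrently in a deeply
sequenced mature produces an isolated ~18–22 nt unipath after arc pruning,
but its KM is roughly (depth × error_rate / 3), far below 50 at realistic
depths, while every genuine mature clears the bar.

## Reclustering

Stage 1 connects candidates sharing an exact 15-mer, comparing forward
k-mers against both orientations of the partner (candidates are
strand-ambiguous, so strand-blind comparison would split clusters). Stage
2 merges stage-1 representatives within global Levenshtein distance ≤ 2,
minimized over orientation (edlib NW mode). Global rather than infix
distance is used because candidates are near-equal length and the
tolerance of 2 describes whole-molecule isomiR variation. Expression ties
break lexicographically for determinism. The two stages never lose a
candidate: final candidates + isomiRs + stage-1 members = input count.

## The 16-mer exclusion filter

Built by counting canonical 16-mers over an "other RNA" collection,
keeping those with count ≥ `filter_min_count` = 5, and subtracting every
16-mer present in a known-mature collection. Both sides are
strand-collapsed, matching the candidates' strand ambiguity. At desk scale
(a few dozen unique decoys) the count floor usually empties the database —
the floor is designed for collections with millions of redundant family
members — so the filter's tests exercise it with repeated inputs.

## Genome mapping and precursor excision

Windows are nonoverlapping 200 bp, indexed by all overlapping forward
12-mers; each window is stored with a 24-nt right extension so a placement
straddling a window boundary is still alignable. Queries run both strands,
semi-globally (free ends on the window, penalized on the candidate), via
edlib's bit-vector implementation; a placement is a hit at edit distance
≤ 2. Hits are deduplicated by genomic span and ranked by (distance,
coverage, chrom, start) with a 100-hit cap.

Exact contiguous seeding has a blind spot the pigeonhole argument misses:
a single substitution at position 10 of a 21-mer intersects *every* 12-mer
window, so a true distance-1 placement can produce no seed. A rescue scan
therefore realigns any candidate whose seeded windows produced no hit
against all windows. This preserves the exhaustive-search contract; its
cost is a full scan for seedless candidates only, which at candidate-set
scale (hundreds of short queries) is negligible.

Precursor excision emits, per configured length L, two placements per hit:
one starting `flank` = 15 bases before the mature, one ending 15 bases
after it — i.e. the mature sits near the 5' or the 3' arm. Windows
truncated by a contig edge are dropped, so hits within ~L of a contig end
yield fewer (possibly zero) precursors. Lengths are kingdom-specific:
[110] for animals, [110, 150, 200, 250, 300] for plants, reflecting the
longer plant precursors.

## Folding engines and the energy window

The built-in engine is a Nussinov-style dynamic program minimizing the sum
of nearest-neighbor stacking energies (Watson–Crick and GU wobble pairs,
approximate Turner stacking values in kcal/mol, destabilizing entries
clamped to 0 so the DP optimum provably equals the minimum additive stack
score over all structures — the equality is tested against exhaustive
enumeration for short sequences). Minimum hairpin loop is 3; pseudoknots
are not generated. Because the model omits loop-destabilization terms its
absolute energies run more negative than a thermodynamic folder: the
validation window for |MFE|, (15, 80) kcal/mol under a thermodynamic
engine, is therefore (25, 200) under the built-in engine, calibrated once
on the shipped synthetic hairpin and random-background fixtures (planted
110-nt hairpins fold near −95 to −120; random 110-mers near −50 to −60 and
are rejected structurally in any case). An RNAfold-backed engine is
selectable (`fold_engine="rnafold"`) when the executable is available, and
an explicitly configured window always takes precedence.

Structure annotation is a standard loop decomposition on the primary
bracket layer: hairpin loops (no nested pairs), bulges (one-sided gap),
internal loops (two-sided), multiloops (≥ 2 children), external loops
(between top-level stems), dangling ends (terminal runs), segments
(top-level helices). Every position receives exactly one class, so element
lengths plus paired positions tile the sequence — asserted as an
invariant. Extra bracket layers contribute only to pseudoknot detection.
The bound "< 3 dangling ends" is vacuous (a linear molecule has at most 2)
and kept for fidelity to the published criteria. A fully unpaired
structure counts one dangling end.

## Random-forest refiner

Feature definitions that the source description leaves open are fixed
normatively here and unit-tested against hand computations: cwf is the
Wootton–Federhen complexity (1/N)·log₄(N!/Π nₐ!); ce is mononucleotide
Shannon entropy in base 4; cm_k is the order-k Markov conditional entropy
of the sequence normalized by log₂4; cl_m is (distinct m-words)/min(4^m,
N−m+1); ct_m is the product of cl_i for i = 1..m; f_m is the mean
reference frequency of the 15-mer's constituent m-mers (mean chosen over
min/max as the least extreme aggregator). Negatives are uniform-random
15-mers excluding positive collisions, seeded. When no frequency tables
are supplied, they are built from the positive *training* split only, so
the hold-out metrics are leakage-free. Candidate-level decision: mean
probability over the candidate's 15-mers, strict threshold 0.5.

## Simulator

Read composition is fixed at 80/10/10 (miRNA / decoy-RNA / genomic).
Per-miRNA weights are log-uniform on [50, 2000] — spanning lowly to highly
expressed molecules — and realized counts are a multinomial draw over the
normalized weights, so counts sum exactly to the class budget. A miRNA
read is the full mature sequence (current platforms capture matures full
length); decoy reads are uniform substrings of length 18–30. The error
model is substitution-only, independent per base, uniform over the three
alternatives; indels are out of scope. Output order and content are
deterministic for a fixed seed.

`make_fixture` screens matures so no two share a 15-mer (either strand)
and no pair is within edit distance 3, which makes truth matching at
tolerance 2 unambiguous. Planted hairpin loci are perfect-stem precursors
(110 nt, 8-nt A/C loop) with the mature 15 nt into the 5' arm — the same
offset the excision flank uses, so a mapped mature excises exactly its
planted hairpin.

## What the synthetic benchmark shows — and does not

The acceptance benchmark (100 screened matures, ~200k reads, error rates
0.01/0.02) exercises the full discovery path at desk scale and verifies
recall ≥ 90% per run and ≥ 97% averaged, with the final candidate count
within [100, 130]. Problem sizes were chosen so the whole benchmark runs
in well under a minute per condition on one CPU. Real sRNA-seq data differ
in ways the simulator does not emulate: adapter remnants, non-uniform
error profiles, isomiR end-heterogeneity, expression distributions with
heavier tails, and true other-RNA families with internal structure and
redundancy (where the 16-mer filter, nearly inert on synthetic decoys,
does real work). Precision on real data is accordingly lower than the
near-1.0 values seen here; recall behavior is the property the synthetic
design is meant to probe. Metrics replacing database-dependent results
(RFAM counts, RF hold-out numbers on curated collections) are asserted as
properties — oracle equivalences, DP confirmations, formula identities —
rather than as reproductions of those numbers.

## Degenerate inputs and tie-breaks

Empty read sets produce empty outputs with a warning, not an error.
Candidate representative ties break on the lexicographically smaller
sequence. Palindromic k-mers (possible at even k) are handled by the
bidirected arc model; palindromic unipaths keep their stored strand.
Chromosomes shorter than the seed length index as a single window with no
seeds. Precursors whose placement leaves the contig are dropped and
logged. The 0/0 cases of precision and recall report 0 with a warning.
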