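"""19-feature representation of 15-mers and the random-forest refiner.

A mature-miRNA candidate of any length is decomposed into overlapping
15-mers; each 15-mer is described by 16 sequence-intrinsic features
(composition, skew, CpG density, and several sequence-complexity measures)
plus 3 features derived from the 6/7/8-mer frequency spectrum of a
reference mature-miRNA collection. A random forest trained on reference
15-mers versus random 15-mers scores candidates; a candidate is kept when
its mean predicted miRNA probability exceeds the decision threshold.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import train_test_split

from .components import Candidate
from .seqio import SeqRecord

KMER_LEN = 15
FEATURE_NAMES = [
    "gc", "gcs", "cpg", "cwf", "ce",
    "cm1", "cm2", "cm3",
    "ct3", "ct4", "ct5", "ct6",
    "cl3", "cl4", "cl5", "cl6",
    "f6", "f7", "f8",
]

_ALPHABET = "ACGT"


def _norm(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= set(_ALPHABET):
        raise ValueError(f"invalid bases: {sorted(set(seq) - set(_ALPHABET))}")
    return seq


@dataclass
class MmerFrequencyTables:
    """Relative m-mer frequencies (m = 6, 7, 8) of a reference mature set."""

    tables: dict[int, dict[str, float]]

    @classmethod
    def from_sequences(cls, seqs: Iterable[SeqRecord | str], ms: Sequence[int] = (6, 7, 8)):
        seq_list = [_norm(s if isinstance(s, str) else s.sequence) for s in seqs]
        tables: dict[int, dict[str, float]] = {}
        for m in ms:
            counts: Counter[str] = Counter()
            for s in seq_list:
                for i in range(len(s) - m + 1):
                    counts[s[i : i + m]] += 1
            total = sum(counts.values())
            tables[m] = {w: c / total for w, c in counts.items()} if total else {}
        return cls(tables)

    @classmethod
    def uniform(cls, ms: Sequence[int] = (6, 7, 8)):
        """Uniform background: every m-mer at 4^-m."""
        return cls({m: {} for m in ms})

    def mean_frequency(self, seq: str, m: int) -> float:
        table = self.tables.get(m, {})
        windows = [seq[i : i + m] for i in range(len(seq) - m + 1)]
        if not table:
            return 4.0 ** -m
        return sum(table.get(w, 0.0) for w in windows) / len(windows)


def _shannon_entropy(seq: str) -> float:
    counts = Counter(seq)
    n = len(seq)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p, 4)
    return h


def _wootton_federhen(seq: str) -> float:
    n = len(seq)
    counts = Counter(seq)
    log4_fact = math.lgamma(n + 1) / math.log(4)
    for c in counts.values():
        log4_fact -= math.lgamma(c + 1) / math.log(4)
    return log4_fact / n


def _markov_conditional_entropy(seq: str, order: int) -> float:
    """Order-k conditional entropy H(next | context), in units of log2(4)."""
    ctx_counts: Counter[str] = Counter()
    trans_counts: Counter[tuple[str, str]] = Counter()
    for i in range(len(seq) - order):
        ctx = seq[i : i + order]
        nxt = seq[i + order]
        ctx_counts[ctx] += 1
        trans_counts[(ctx, nxt)] += 1
    total = sum(ctx_counts.values())
    h = 0.0
    for ctx, cc in ctx_counts.items():
        p_ctx = cc / total
        h_ctx = 0.0
        for b in _ALPHABET:
            tc = trans_counts.get((ctx, b), 0)
            if tc:
                p = tc / cc
                h_ctx -= p * math.log2(p)
        h += p_ctx * h_ctx
    return h / 2.0  # log2(|alphabet|) = 2


def _distinct_words(seq: str, m: int) -> int:
    return len({seq[i : i + m] for i in range(len(seq) - m + 1)})


def _linguistic(seq: str, m: int) -> float:
    possible = min(4 ** m, len(seq) - m + 1)
    return _distinct_words(seq, m) / possible


def _trifonov(seq: str, m: int) -> float:
    prod = 1.0
    for i in range(1, m + 1):
        prod *= _linguistic(seq, i)
    return prod


def compute_features(kmer15: str, tables: MmerFrequencyTables) -> np.ndarray:
    """The 19-feature vector of a single 15-mer (order: FEATURE_NAMES)."""
    seq = _norm(kmer15)
    if len(seq) != KMER_LEN:
        raise ValueError(f"expected a {KMER_LEN}-mer, got length {len(seq)}")
    counts = Counter(seq)
    g, c = counts.get("G", 0), counts.get("C", 0)
    gc = (g + c) / KMER_LEN
    gcs = (g - c) / (g + c) if (g + c) else 0.0
    cpg = sum(1 for i in range(KMER_LEN - 1) if seq[i : i + 2] == "CG") / (KMER_LEN - 1)
    feats = [
        gc,
        gcs,
        cpg,
        _wootton_federhen(seq),
        _shannon_entropy(seq),
        _markov_conditional_entropy(seq, 1),
        _markov_conditional_entropy(seq, 2),
        _markov_conditional_entropy(seq, 3),
        _trifonov(seq, 3),
        _trifonov(seq, 4),
        _trifonov(seq, 5),
        _trifonov(seq, 6),
        _linguistic(seq, 3),
        _linguistic(seq, 4),
        _linguistic(seq, 5),
        _linguistic(seq, 6),
        tables.mean_frequency(seq, 6),
        tables.mean_frequency(seq, 7),
        tables.mean_frequency(seq, 8),
    ]
    return np.asarray(feats, dtype=float)


def feature_matrix(kmers: Iterable[str], tables: MmerFrequencyTables) -> np.ndarray:
    return np.vstack([compute_features(k, tables) for k in kmers])


def random_kmers(n: int, rng: np.random.Generator, length: int = KMER_LEN,
                 exclude: set[str] | None = None) -> list[str]:
    exclude = exclude or set()
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        kmer = "".join(rng.choice(list(_ALPHABET), size=length))
        if kmer in exclude or kmer in seen:
            continue
        seen.add(kmer)
        out.append(kmer)
    return out


def build_training_set(
    mirnas: Iterable[SeqRecord | str], rng_seed: int = 42
) -> tuple[list[str], list[str]]:
    """(positive, negative) 15-mer sets for classifier training.

    Positives: all distinct 15-mer substrings of the mature collection.
    Negatives: an equal number of seeded uniform-random 15-mers, excluding
    collisions with the positives.
    """
    positives: list[str] = []
    seen: set[str] = set()
    for rec in mirnas:
        seq = _norm(rec if isinstance(rec, str) else rec.sequence)
        for i in range(len(seq) - KMER_LEN + 1):
            w = seq[i : i + KMER_LEN]
            if w not in seen:
                seen.add(w)
                positives.append(w)
    if not positives:
        raise ValueError("no mature sequences of length >= 15 provided")
    rng = np.random.default_rng(rng_seed)
    negatives = random_kmers(len(positives), rng, exclude=seen)
    return positives, negatives


@dataclass
class RfModel:
    forest: RandomForestClassifier
    tables: MmerFrequencyTables
    rng_seed: int
    n_trees: int
    split: float
    accuracy: float
    precision: float
    recall: float
    feature_importances: dict[str, float]

    def predict_proba(self, kmers: Sequence[str]) -> np.ndarray:
        x = feature_matrix(kmers, self.tables)
        return self.forest.predict_proba(x)[:, 1]


def train_rf(
    positives: Sequence[str],
    negatives: Sequence[str],
    tables: MmerFrequencyTables | None = None,
    split: float = 0.75,
    n_trees: int = 500,
    rng_seed: int = 42,
) -> RfModel:
    """Train the refiner forest with a stratified hold-out evaluation.

    ``split`` is the training fraction (held-out fraction = 1 - split).
    When no frequency tables are given they are built from the positive
    training portion only, avoiding leakage into the hold-out metrics.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be nonempty")
    kmers = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    idx = np.arange(len(kmers))
    idx_train, idx_test = train_test_split(
        idx, train_size=split, stratify=y, random_state=rng_seed
    )
    if tables is None:
        tables = MmerFrequencyTables.from_sequences(
            [kmers[i] for i in idx_train if y[i] == 1]
        )
    x = feature_matrix(kmers, tables)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed, n_jobs=1)
    forest.fit(x[idx_train], y[idx_train])
    pred = forest.predict(x[idx_test])
    model = RfModel(
        forest=forest,
        tables=tables,
        rng_seed=rng_seed,
        n_trees=n_trees,
        split=split,
        accuracy=float(accuracy_score(y[idx_test], pred)),
        precision=float(precision_score(y[idx_test], pred, zero_division=0)),
        recall=float(recall_score(y[idx_test], pred, zero_division=0)),
        feature_importances=dict(zip(FEATURE_NAMES, map(float, forest.feature_importances_))),
    )
    return model


def classify_candidates(
    candidates: Sequence[Candidate],
    model,
    threshold: float = 0.5,
) -> tuple[list[Candidate], list[Candidate]]:
    """Keep a candidate iff the mean 15-mer miRNA probability exceeds
    ``threshold`` (strict inequality)."""
    kept: list[Candidate] = []
    rejected: list[Candidate] = []
    for cand in candidates:
        kmers = [
            cand.sequence[i : i + KMER_LEN]
            for i in range(len(cand.sequence) - KMER_LEN + 1)
        ]
        score = float(np.mean(model.predict_proba(kmers)))
        (kept if score > threshold else rejected).append(cand)
    return kept, rejected
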