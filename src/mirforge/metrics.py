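"""Benchmark metrics: prediction/truth matching and precision/recall/F.

A prediction is a true positive when some ground-truth mature sequence is
within the matching edit distance (minimized over orientation, matching
the pipeline's own isomiR tolerance; set ``max_edit=0`` for exact
matching). Each truth sequence counts once for false-negative accounting
no matter how many predictions hit it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .recluster import edit_distance

log = logging.getLogger("mirforge")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_truth: set[int]  # indices into the truth list
    unmatched_predictions: list[str]


def match_predictions(
    predictions: Sequence[str], truth: Sequence[str], max_edit: int = 2
) -> MatchResult:
    """Classify predictions into TP/FP and truth into found/missed."""
    matched_truth: set[int] = set()
    tp = 0
    fps: list[str] = []
    for pred in predictions:
        hits = [
            t_idx
            for t_idx, t_seq in enumerate(truth)
            if edit_distance(pred, t_seq) <= max_edit
        ]
        if hits:
            tp += 1
            matched_truth.update(hits)
        else:
            fps.append(pred)
    fn = len(truth) - len(matched_truth)
    return MatchResult(tp=tp, fp=len(fps), fn=fn, matched_truth=matched_truth,
                       unmatched_predictions=fps)


@dataclass
class BenchmarkResult:
    precision: float
    recall: float
    f_score: float


def scores(tp: int, fp: int, fn: int) -> BenchmarkResult:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F = harmonic mean.

    0/0 cases return 0 with a logged warning.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        log.warning("precision undefined (no predictions); reporting 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("recall undefined (empty truth); reporting 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return BenchmarkResult(precision=precision, recall=recall, f_score=f)


def evaluate(predictions: Iterable[str], truth: Iterable[str], max_edit: int = 2) -> BenchmarkResult:
    m = match_predictions(list(predictions), list(truth), max_edit)
    return scores(m.tp, m.fp, m.fn)
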