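"""Label binarization, decision-level fusion, folds and metrics.

Self-report ratings (1-9) binarize at five: rating > 5 is "high".  Three
per-modality classifiers (video, EEG, physiological) are fused either by
majority vote or by a weighted sum of class probabilities,

    p_o^x = a p_video^x + b p_EEG^x + c p_physio^x,   a + b + c = 1,

with the weights searched exhaustively on a 0.01 grid over the simplex
(5,151 candidate triples) to maximize the training F-score.  Evaluation
uses leave-some-subject-out cross-validation: subjects are shuffled into
six folds, every trial of a test subject is unseen at training, and the
reported metrics are the unweighted mean over folds.  "High" is the
positive class throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .classifiers import ProbabilityPair

PairLike = Union[ProbabilityPair, np.ndarray, Sequence[float]]


@dataclass(frozen=True)
class FusionWeights:
    """(video, EEG, physiological) weights on the probability simplex.

    The weight search only ever produces triples on the 0.01 grid, but
    arbitrary simplex triples are accepted so e.g. uniform (1/3, 1/3,
    1/3) fusion can be expressed.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fusion weights must lie in [0, 1]")
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


@dataclass(frozen=True)
class FoldPlan:
    """Subject-level fold assignments: (train subjects, test subjects)."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def binarize_rating(rating: int) -> int:
    """SAM rating (1-9) -> binary label with five as the threshold.

    rating > 5 -> 1 (high); rating <= 5 -> 0 (low).
    """
    rating = int(rating)
    if not 1 <= rating <= 9:
        raise ValueError(f"rating {rating} outside the 1-9 SAM scale")
    return 1 if rating > 5 else 0


def majority_vote(votes: Sequence[int]) -> int:
    """Majority of exactly three binary votes (no ties possible)."""
    if len(votes) != 3:
        raise ValueError("majority vote takes exactly 3 predictions")
    votes = [int(v) for v in votes]
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be binary")
    return 1 if sum(votes) >= 2 else 0


def _as_pair_array(p: PairLike) -> np.ndarray:
    if isinstance(p, ProbabilityPair):
        return p.as_array()
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise ValueError("probability pair must have two entries")
    return arr


def weighted_fusion(
    p_video: PairLike, p_eeg: PairLike, p_physio: PairLike, w: FusionWeights
) -> tuple[ProbabilityPair, int]:
    """Weighted-sum fusion of three probability pairs; decision = argmax.

    A fused probability of exactly 0.5 resolves to "high".
    """
    fused = (w.a * _as_pair_array(p_video) + w.b * _as_pair_array(p_eeg)
             + w.c * _as_pair_array(p_physio))
    pair = ProbabilityPair(p_low=float(fused[0]), p_high=float(fused[1]),
                           modality="fused")
    return pair, pair.decision


def _grid() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (a, b, c) triples on the 0.01 simplex grid, in lexicographic
    (a, b) order."""
    a_list, b_list = [], []
    for a in range(101):
        for b in range(101 - a):
            a_list.append(a)
            b_list.append(b)
    a_arr = np.array(a_list, dtype=float) / 100.0
    b_arr = np.array(b_list, dtype=float) / 100.0
    return a_arr, b_arr, 1.0 - a_arr - b_arr


def fusion_grid_size() -> int:
    return _grid()[0].size


def search_fusion_weights(
    p_video: np.ndarray, p_eeg: np.ndarray, p_physio: np.ndarray,
    labels: Sequence[int],
) -> FusionWeights:
    """Exhaustive 0.01-grid search for the F-score-maximizing weights.

    Inputs are (n, 2) per-modality probability arrays over the training
    trials.  Ties resolve to the lexicographically smallest (a, b).
    """
    pv = np.asarray(p_video, dtype=float)[:, 1]
    pe = np.asarray(p_eeg, dtype=float)[:, 1]
    pp = np.asarray(p_physio, dtype=float)[:, 1]
    y = np.asarray(labels, dtype=int)
    if not (pv.shape == pe.shape == pp.shape == y.shape):
        raise ValueError("all three modalities must be predicted for every trial")
    a, b, c = _grid()
    fused = a[:, None] * pv[None] + b[:, None] * pe[None] + c[:, None] * pp[None]
    dec = fused >= 0.5
    pos = y == 1
    tp = (dec & pos).sum(axis=1)
    fp = (dec & ~pos).sum(axis=1)
    fn = (~dec & pos).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    best = int(np.argmax(f1))  # argmax returns the first (lexicographic) max
    return FusionWeights(a=round(a[best], 2), b=round(b[best], 2), c=round(c[best], 2))


def make_folds(subject_ids: Sequence[str], n_folds: int = 6, seed: int = 0) -> FoldPlan:
    """Shuffle subjects (seeded) and deal them into near-equal test groups."""
    uniq = list(dict.fromkeys(subject_ids))
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    base, extra = divmod(len(order), n_folds)
    folds = []
    start = 0
    for k in range(n_folds):
        size = base + (1 if k < extra else 0)
        test = tuple(order[start : start + size])
        train = tuple(s for s in order if s not in test)
        folds.append((train, test))
        start += size
    return FoldPlan(folds=tuple(folds))


def confusion_and_metrics(
    predictions: Sequence[int], labels: Sequence[int]
) -> tuple[ConfusionCounts, MetricSet]:
    """Confusion counts and accuracy/precision/recall/F1 ("high" positive).

    Undefined precision or recall (empty denominator) is reported as 0.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    metrics = MetricSet(accuracy=(tp + tn) / counts.n, precision=precision,
                        recall=recall, f1=f1)
    return counts, metrics


def average_metrics(metric_sets: Sequence[MetricSet]) -> MetricSet:
    """Unweighted mean of per-fold metrics (the reported result)."""
    if not metric_sets:
        raise ValueError("no metrics to average")
    return MetricSet(
        accuracy=float(np.mean([m.accuracy for m in metric_sets])),
        precision=float(np.mean([m.precision for m in metric_sets])),
        recall=float(np.mean([m.recall for m in metric_sets])),
        f1=float(np.mean([m.f1 for m in metric_sets])),
    )
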