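"""Cost-sensitive per-modality classifiers over feature sequences.

Two classification routes are offered.  The sequence route feeds the
per-window feature vectors to a stacked LSTM (80 then 30 units) that
keeps the temporal structure.  The flat route collapses each trial to
the mean of its window features and fits a classical model: an RBF-SVM
(C = 200), a 5-nearest-neighbour voter, or a 500-tree random forest.
Class imbalance is handled throughout with "balanced" class weights,
``w_c = N / (2 N_c)``, which equalize the weighted class masses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.class_weight import compute_class_weight

from ._net.lstm import StackedLstm
from .features import WindowedFeatureSequence


@dataclass(frozen=True)
class ClassWeights:
    """Balanced class weights; weighted class masses are equal."""

    weight_low: float
    weight_high: float

    def __post_init__(self) -> None:
        if self.weight_low <= 0 or self.weight_high <= 0:
            raise ValueError("class weights must be positive")

    def as_dict(self) -> dict[int, float]:
        return {0: self.weight_low, 1: self.weight_high}

    def sample_weights(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype=int)
        return np.where(labels == 1, self.weight_high, self.weight_low)


@dataclass(frozen=True)
class ProbabilityPair:
    """One classifier's class-probability vector over {low, high}."""

    p_low: float
    p_high: float
    modality: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_low <= 1 and 0 <= self.p_high <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_low + self.p_high - 1.0) > 1e-6:
            raise ValueError("probability pair must sum to 1")

    @property
    def decision(self) -> int:
        return 1 if self.p_high >= 0.5 else 0

    def as_array(self) -> np.ndarray:
        return np.array([self.p_low, self.p_high])


@dataclass(frozen=True)
class LstmSpec:
    """Stacked-LSTM hyper-parameters (80/30 units, 100 epochs, Adam with a
    reduce-on-plateau learning rate from 1e-3 down to 1e-4, factor 0.5)."""

    layer1_units: int = 80
    layer2_units: int = 30
    epochs: int = 100
    batch_size: int = 32
    lr_start: float = 1e-3
    lr_floor: float = 1e-4
    lr_decay_factor: float = 0.5
    patience: int = 5
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_floor <= self.lr_start:
            raise ValueError("need 0 < lr_floor <= lr_start")


#: Batch sizes used when training the LSTM per modality.
LSTM_BATCH_SIZES = {"eeg": 128, "gsr": 32, "ppg": 64, "physio": 32}


@dataclass(frozen=True)
class ClassicalSpec:
    """Grid-search winners for the flat-vector classifiers."""

    svm_c: float = 200.0
    knn_neighbors: int = 5
    rf_trees: int = 500
    seed: int = 0


def compute_class_weights(labels: Sequence[int]) -> ClassWeights:
    """Balanced weights ``w_c = N_total / (2 N_c)`` for binary labels."""
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("both classes (0=low, 1=high) must be present")
    w = compute_class_weight("balanced", classes=classes, y=y)
    return ClassWeights(weight_low=float(w[0]), weight_high=float(w[1]))


def stack_sequences(sequences: Sequence[WindowedFeatureSequence | np.ndarray]) -> np.ndarray:
    arrays = [s.windows if isinstance(s, WindowedFeatureSequence) else np.asarray(s)
              for s in sequences]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"ragged sequences: window/feature shapes {sorted(shapes)}")
    return np.stack(arrays)


def flatten_sequences(sequences: Sequence[WindowedFeatureSequence | np.ndarray]) -> np.ndarray:
    """Per-trial flat vector: mean of the per-window features."""
    return stack_sequences(sequences).mean(axis=1)


class LstmModel:
    """Sequence classifier: feature z-scoring + stacked LSTM."""

    def __init__(self, net: StackedLstm, spec: LstmSpec,
                 mu: np.ndarray, sd: np.ndarray) -> None:
        self.net = net
        self.spec = spec
        self.mu = mu
        self.sd = sd

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sd

    def predict_proba(self, sequences) -> np.ndarray:
        return self.net.predict_proba(self._scale(stack_sequences(sequences)))

    @property
    def history(self):
        return self.net.history

    def save(self, path) -> None:
        self.net.save(path)
        np.savez(str(path) + ".scaler.npz", mu=self.mu, sd=self.sd)


def _validation_indices(n: int, subject_ids: Optional[Sequence[str]]) -> np.ndarray:
    """Last 20% of the training trials, grouped by subject when known."""
    if subject_ids is None:
        k = max(1, int(round(0.2 * n)))
        return np.arange(n - k, n)
    subject_ids = list(subject_ids)
    uniq = list(dict.fromkeys(subject_ids))
    k = max(1, int(round(0.2 * len(uniq))))
    val_subjects = set(uniq[-k:])
    return np.flatnonzero([s in val_subjects for s in subject_ids])


def train_lstm(
    sequences: Sequence[WindowedFeatureSequence | np.ndarray],
    labels: Sequence[int],
    weights: ClassWeights,
    spec: LstmSpec = LstmSpec(),
    subject_ids: Optional[Sequence[str]] = None,
) -> LstmModel:
    """Train the stacked LSTM on per-window feature sequences."""
    x = stack_sequences(sequences)
    y = np.asarray(labels, dtype=int)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 training trials per class")
    mu = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    sd = np.where(sd > 0, sd, 1.0)
    net = StackedLstm(n_features=x.shape[2],
                      units=(spec.layer1_units, spec.layer2_units), seed=spec.seed)
    model = LstmModel(net, spec, mu, sd)
    net.fit(
        model._scale(x), y, weights.sample_weights(y),
        epochs=spec.epochs, batch_size=spec.batch_size,
        lr_start=spec.lr_start, lr_floor=spec.lr_floor,
        lr_decay_factor=spec.lr_decay_factor, patience=spec.patience,
        min_delta=spec.min_delta,
        val_indices=_validation_indices(x.shape[0], subject_ids),
    )
    return model


class WeightedVoteKnn:
    """KNN whose neighbour-vote fractions are re-weighted by class weights.

    KNN has no native cost-sensitive training, so the vote fractions are
    multiplied by the class weights and renormalized; with unit weights
    this reduces to plain vote fractions.
    """

    def __init__(self, n_neighbors: int, weights: ClassWeights) -> None:
        self._pipe = Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=n_neighbors)),
        ])
        self._weights = weights
        self.classes_ = np.array([0, 1])

    def fit(self, x, y):
        self._pipe.fit(x, y)
        return self

    def predict_proba(self, x) -> np.ndarray:
        votes = self._pipe.predict_proba(x)
        if votes.shape[1] == 1:  # degenerate single-class fit
            votes = np.hstack([votes, np.zeros_like(votes)])
        w = np.array([self._weights.weight_low, self._weights.weight_high])
        p = votes * w
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def train_classical(
    features: np.ndarray,
    labels: Sequence[int],
    weights: ClassWeights,
    which: str,
    spec: ClassicalSpec = ClassicalSpec(),
):
    """Fit an SVM/KNN/RF on flat per-trial feature vectors.

    All models expose ``predict_proba`` over {low, high}; inputs are
    z-scored inside the pipeline.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2:
        raise ValueError("features must be (n_trials, n_features)")
    if which == "svm":
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=spec.svm_c, probability=True,
                        class_weight=weights.as_dict(), random_state=spec.seed)),
        ])
    elif which == "knn":
        model = WeightedVoteKnn(spec.knn_neighbors, weights)
    elif which == "rf":
        model = Pipeline([
            ("scale", StandardScaler()),
            ("rf", RandomForestClassifier(n_estimators=spec.rf_trees,
                                          class_weight=weights.as_dict(),
                                          random_state=spec.seed)),
        ])
    else:
        raise ValueError(f"unknown classifier {which!r}; use svm, knn or rf")
    model.fit(x, y)
    return model


def to_pairs(probs: np.ndarray, modality: str,
             trial_ids: Optional[Sequence[str]] = None) -> list[ProbabilityPair]:
    """Wrap an (n, 2) probability array as ProbabilityPair records."""
    probs = np.asarray(probs, dtype=float)
    ids = trial_ids if trial_ids is not None else [""] * probs.shape[0]
    return [ProbabilityPair(p_low=float(p[0]), p_high=float(p[1]),
                            modality=modality, trial_id=t)
            for p, t in zip(probs, ids)]
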