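"""Per-timepoint labeling, trial splitting, and linear SVM decoding.

Every sample is one instance, labeled +1 while a task block is on and -1
during rest.  Training uses the first half of trials (ceiling rule for odd
counts), testing the second half; the boundary sits at the first test
block's onset, with the intervening rest assigned to the training half.
The classifier is a soft-margin linear SVM (hinge loss, penalty C = 128 by
default); predictions are sign(w.x + b) with a decision value of exactly 0
mapped to -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .features import FeatureMatrix, FeatureSpec
from .io import EventSchedule

__all__ = [
    "TrialSplit",
    "TrainedModel",
    "label_timepoints",
    "split_trials",
    "train_classifier",
    "predict",
]

DEFAULT_C = 128.0


def label_timepoints(events: EventSchedule, n_samples: int, fs: float,
                     t0_s: float = 0.0) -> np.ndarray:
    """Behavioral ground-truth labels: +1 iff onset <= t_k < onset + duration."""
    end_time = t0_s + n_samples / fs
    for onset, dur in events.blocks:
        if onset + dur > end_time + 1e-9:
            raise ValueError(
                f"block ({onset}, {dur}) extends past recording end {end_time:.3f} s")
    labels = np.full(n_samples, -1, dtype=int)
    for onset, dur in events.blocks:
        lo = int(np.ceil((onset - t0_s) * fs - 1e-9))
        hi = int(np.ceil((onset - t0_s + dur) * fs - 1e-9))
        labels[max(lo, 0):min(hi, n_samples)] = 1
    return labels


@dataclass(frozen=True)
class TrialSplit:
    """First-half-train / second-half-test partition of a block schedule."""

    train_blocks: tuple[int, ...]
    test_blocks: tuple[int, ...]
    train_range: tuple[int, int]  # half-open sample intervals
    test_range: tuple[int, int]


def split_trials(events: EventSchedule, n_samples: int, fs: float) -> TrialSplit:
    """Assign the first ceil(n/2) blocks (plus surrounding rest) to training.

    The sample boundary is the first test block's onset; rest between the
    halves belongs to the earlier (training) half.
    """
    n_blocks = events.n_blocks
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks to split")
    n_train = int(np.ceil(n_blocks / 2))
    boundary = int(np.ceil(events.blocks[n_train][0] * fs - 1e-9))
    return TrialSplit(
        train_blocks=tuple(range(n_train)),
        test_blocks=tuple(range(n_train, n_blocks)),
        train_range=(0, boundary),
        test_range=(boundary, n_samples),
    )


@dataclass
class TrainedModel:
    """Linear decision rule: predict sign(weights . x + bias), 0 -> -1."""

    weights: np.ndarray
    bias: float
    C: float
    feature_spec: FeatureSpec | None = None
    column_names: list[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model {self.weights.shape[0]}, data {X.shape[1]}")
        return X @ self.weights + self.bias


def train_classifier(X: FeatureMatrix | np.ndarray, y: np.ndarray,
                     C: float = DEFAULT_C,
                     row_mask: np.ndarray | None = None,
                     feature_spec: FeatureSpec | None = None) -> TrainedModel:
    """Fit a soft-margin linear SVM on the valid rows.

    The fit is deterministic given the data (liblinear dual coordinate
    descent with a fixed permutation seed, tolerance 1e-6); the reported
    solution has no random-initialization dependence.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if isinstance(X, FeatureMatrix):
        names = list(X.column_names)
        mask = X.valid.copy()
        X = X.X
    else:
        names = []
        mask = np.ones(X.shape[0], dtype=bool)
    if row_mask is not None:
        mask &= row_mask
    if X.shape[1] == 0:
        raise ValueError("empty feature space")
    Xf, yf = X[mask], np.asarray(y)[mask]
    classes = np.unique(yf)
    if Xf.shape[0] < 2 or classes.size < 2:
        raise ValueError("training data must contain both classes (>= 2 rows)")

    svc = LinearSVC(loss="hinge", C=C, tol=1e-6, max_iter=5_000_000,
                    random_state=0)
    svc.fit(Xf, yf)
    return TrainedModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        feature_spec=feature_spec,
        column_names=names,
    )


def predict(model: TrainedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-row labels in {+1, -1}; invalid rows emit -1.

    Stateless per row: predictions are invariant to row order.
    """
    if isinstance(X, FeatureMatrix):
        valid = X.valid
        X = X.X
    else:
        valid = np.ones(X.shape[0], dtype=bool)
    labels = np.full(X.shape[0], -1, dtype=int)
    if valid.any():
        d = model.decision_values(np.where(np.isnan(X), 0.0, X)[valid])
        labels[valid] = np.where(d > 0, 1, -1)
    return labels
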