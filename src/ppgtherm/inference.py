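"""Classifiers and leave-one-subject-out evaluation.

Two model families are evaluated on 20-second windows: single-hidden-layer
neural networks (80 hidden units = NN1, 260 = NN2; sigmoid activations,
per-sample SGD at learning rate 0.5 for 100 epochs) trained on *low-level*
features (fixed-length encodings of the raw PP-interval and thermal
variability sequences), and a 1-nearest-neighbour benchmark on the nine
hand-engineered features.  Evaluation is leave-one-subject-out (LOSO):
one fold per participant, training data z-scored by the training split's
mean/SD and the same transform applied to the held-out participant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from .errors import InvalidInputError
from .features import prv_features, thermal_features
from .signals import MeasurementWindow

__all__ = [
    "ModelSpec",
    "NNModel",
    "CvReport",
    "encode_low_level",
    "build_feature_matrix",
    "fit_nn",
    "knn1_classify",
    "loso_cv",
]

logger = logging.getLogger(__name__)

MODALITIES = ("multimodal", "ppg_only", "thermal_only")
LEVELS = ("low", "high")

DEFAULT_PP_LEN = 40
DEFAULT_TV_LEN = 20


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to run: kind 'nn' (with hidden_size) or 'knn'."""

    kind: str = "nn"
    hidden_size: int = 260

    def __post_init__(self):
        if self.kind not in ("nn", "knn"):
            raise InvalidInputError(f"unknown model kind {self.kind!r}")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def encode_low_level(window: MeasurementWindow, modality: str = "multimodal",
                     pp_len: int = DEFAULT_PP_LEN,
                     tv_len: int = DEFAULT_TV_LEN) -> np.ndarray | None:
    """Fixed-length low-level feature row for one window.

    PP intervals (ms) are linearly interpolated over the beat index to
    ``pp_len`` points; the scaled thermal sequence is truncated or edge-padded
    to ``tv_len``.  Multimodal rows concatenate both.  Returns None (window
    excluded, reason logged) when a required modality is empty.
    """
    if modality not in MODALITIES:
        raise InvalidInputError(f"unknown modality {modality!r}")
    parts = []
    if modality in ("multimodal", "ppg_only"):
        if window.pp is None or len(window.pp.valid_intervals) < 2:
            logger.info(
                "excluding window %s/%s: empty PP series",
                window.participant_id, window.session_id,
            )
            return None
        iv = window.pp.valid_intervals
        parts.append(np.interp(np.linspace(0.0, len(iv) - 1.0, pp_len),
                               np.arange(len(iv), dtype=float), iv))
    if modality in ("multimodal", "thermal_only"):
        if window.tv is None or len(window.tv) == 0:
            logger.info(
                "excluding window %s/%s: empty thermal sequence",
                window.participant_id, window.session_id,
            )
            return None
        v = window.tv.values
        if len(v) >= tv_len:
            parts.append(v[:tv_len])
        else:
            parts.append(np.concatenate(
                [v, np.full(tv_len - len(v), v[-1])]))
    return np.concatenate(parts)


def encode_high_level(window: MeasurementWindow,
                      modality: str = "multimodal") -> np.ndarray | None:
    """Nine engineered features (6 PRV + 3 thermal) for one window."""
    if modality not in MODALITIES:
        raise InvalidInputError(f"unknown modality {modality!r}")
    parts = []
    if modality in ("multimodal", "ppg_only"):
        if window.pp is None:
            return None
        vec = prv_features(window.pp)
        if vec.missing:
            logger.info(
                "excluding window %s/%s: missing PRV features",
                window.participant_id, window.session_id,
            )
            return None
        parts.append(vec.as_array())
    if modality in ("multimodal", "thermal_only"):
        if window.tv is None:
            return None
        parts.append(thermal_features(window.tv).as_array())
    return np.concatenate(parts)


def build_feature_matrix(windows: list[MeasurementWindow],
                         modality: str = "multimodal", level: str = "low",
                         pp_len: int = DEFAULT_PP_LEN,
                         tv_len: int = DEFAULT_TV_LEN):
    """Encode windows into (X, y, groups), dropping unencodable windows.

    ``y`` is 1 for Stress, 0 for No-Stress; ``groups`` the participant ids.
    """
    if level not in LEVELS:
        raise InvalidInputError(f"unknown level {level!r}")
    rows, labels, groups = [], [], []
    for w in windows:
        if w.label is None:
            raise InvalidInputError(
                f"window {w.participant_id}/{w.session_id} has no label"
            )
        row = (encode_low_level(w, modality, pp_len, tv_len) if level == "low"
               else encode_high_level(w, modality))
        if row is None:
            continue
        rows.append(row)
        labels.append(int(w.label))
        groups.append(w.participant_id)
    if not rows:
        raise InvalidInputError("no encodable windows")
    return np.vstack(rows), np.asarray(labels), np.asarray(groups)


@dataclass
class NNModel:
    """Single-hidden-layer sigmoid network trained by per-sample SGD."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    mean: np.ndarray
    sd: np.ndarray
    hidden_size: int
    seed: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.sd
        hidden = _sigmoid(Z @ self.w1 + self.b1)
        return _sigmoid(hidden @ self.w2 + self.b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _zscore_params(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through unscaled
    return mean, sd


def fit_nn(X: np.ndarray, y: np.ndarray, hidden_size: int = 260,
           seed: int = 0, lr: float = 0.5, epochs: int = 100) -> NNModel:
    """Train the single-hidden-layer network.

    Inputs are z-scored by the training mean/SD (stored in the model and
    reused verbatim on test data).  Weights start uniform(-0.1, 0.1) from
    ``seed``; training is plain per-sample stochastic gradient descent on
    binary cross-entropy, samples reshuffled each epoch with the same
    generator, sigmoid hidden and output units, decision threshold 0.5.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidInputError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidInputError("training data contains a single class")
    mean, sd = _zscore_params(X)
    Z = (X - mean) / sd
    n, d = Z.shape
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.1, 0.1, size=(d, hidden_size))
    b1 = rng.uniform(-0.1, 0.1, size=hidden_size)
    w2 = rng.uniform(-0.1, 0.1, size=hidden_size)
    b2 = float(rng.uniform(-0.1, 0.1))
    for _ in range(epochs):
        for i in rng.permutation(n):
            x = Z[i]
            h = _sigmoid(x @ w1 + b1)
            out = _sigmoid(h @ w2 + b2)
            # BCE + sigmoid output: output delta is (out - y)
            d_out = out - y[i]
            d_h = d_out * w2 * h * (1.0 - h)
            w2 -= lr * d_out * h
            b2 -= lr * d_out
            w1 -= lr * np.outer(x, d_h)
            b1 -= lr * d_h
    return NNModel(w1, b1, w2, b2, mean, sd, hidden_size, seed)


def knn1_classify(train_X: np.ndarray, train_y: np.ndarray,
                  test_X: np.ndarray) -> np.ndarray:
    """1-nearest-neighbour prediction, ties to the earliest training row.

    Expects features already z-scored by the training mean/SD (the LOSO
    harness does this).  Distances are Euclidean; ``argmin`` returns the
    first minimum, realising the earliest-index tie rule.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.ndim != 2 or len(train_X) == 0:
        raise InvalidInputError("training set must be a non-empty 2-D array")
    if test_X.shape[1] != train_X.shape[1]:
        raise InvalidInputError(
            f"dimension mismatch: train {train_X.shape[1]}, "
            f"test {test_X.shape[1]}"
        )
    d2 = ((test_X[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    return np.asarray(train_y)[nearest]


@dataclass
class CvReport:
    """Leave-one-subject-out evaluation summary."""

    fold_participants: list[str]
    fold_accuracies: list[float]
    fold_f1: list[float]
    confusion: np.ndarray  # rows true (0,1), cols predicted (0,1), counts
    skipped_folds: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def mean_f1(self) -> float:
        vals = [f for f in self.fold_f1 if not np.isnan(f)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "fold_participants": list(self.fold_participants),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "fold_f1": [float(f) for f in self.fold_f1],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
            "confusion": self.confusion.tolist(),
            "skipped_folds": list(self.skipped_folds),
        }

    def summary(self) -> str:
        c = self.confusion
        return (
            f"LOSO over {len(self.fold_accuracies)} folds: "
            f"mean accuracy {100 * self.mean_accuracy:.2f}% "
            f"(SD {100 * self.sd_accuracy:.2f}), "
            f"mean F1 {100 * self.mean_f1:.2f}%\n"
            f"confusion (rows=true NoStress/Stress, cols=pred): "
            f"[[{c[0, 0]}, {c[0, 1]}], [{c[1, 0]}, {c[1, 1]}]]"
        )


def loso_cv(windows: list[MeasurementWindow],
            model_spec: ModelSpec = ModelSpec(),
            modality: str = "multimodal", level: str | None = None,
            seed: int = 0, exclude_sessions: tuple[str, ...] = (),
            pp_len: int = DEFAULT_PP_LEN,
            tv_len: int = DEFAULT_TV_LEN) -> CvReport:
    """Leave-one-subject-out cross-validation.

    One fold per participant: train on every other participant's windows,
    test on the held-out participant.  ``level`` defaults to the model's
    natural pairing (low-level sequences for the NNs, the nine engineered
    features for kNN).  ``exclude_sessions`` drops named sessions (e.g.
    'Rest1') before folding.  Reports per-fold accuracy and macro F1, their
    means, and the confusion matrix accumulated over folds.
    """
    if level is None:
        level = "low" if model_spec.kind == "nn" else "high"
    kept = [w for w in windows if w.session_id not in exclude_sessions]
    X, y, groups = build_feature_matrix(kept, modality, level, pp_len, tv_len)
    participants = list(dict.fromkeys(groups))  # stable order
    if len(participants) < 3:
        raise InvalidInputError("LOSO needs at least 3 participants")
    fold_parts, fold_acc, fold_f1, skipped = [], [], [], []
    confusion = np.zeros((2, 2), dtype=int)
    for fold_idx, pid in enumerate(participants):
        test_mask = groups == pid
        if not test_mask.any():
            skipped.append(pid)
            logger.warning("skipping fold for %s: no windows", pid)
            continue
        X_tr, y_tr = X[~test_mask], y[~test_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        if model_spec.kind == "nn":
            model = fit_nn(X_tr, y_tr, model_spec.hidden_size,
                           seed=seed + fold_idx)
            pred = model.predict(X_te)
        else:
            mean, sd = _zscore_params(X_tr)
            pred = knn1_classify((X_tr - mean) / sd, y_tr,
                                 (X_te - mean) / sd)
        fold_parts.append(pid)
        fold_acc.append(float(np.mean(pred == y_te)))
        if len(np.unique(y_te)) < 2 and np.array_equal(pred, y_te):
            # macro F1 undefined when a class is absent and never predicted
            fold_f1.append(float("nan"))
            logger.info("fold %s: macro F1 undefined, skipped", pid)
        else:
            fold_f1.append(float(f1_score(y_te, pred, average="macro",
                                          zero_division=0)))
        confusion += confusion_matrix(y_te, pred, labels=[0, 1])
    return CvReport(fold_parts, fold_acc, fold_f1, confusion, skipped)
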