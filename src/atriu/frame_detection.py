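"""Mitral valve-state classification and end-systolic frame selection.

A frame is classified as "closed" (positive class) or "open"; the ES frame is
the last frame of the largest block of consecutive closed states.  The
classifier is a small multilayer perceptron on downsampled frames, optimized
by stochastic gradient descent with momentum under cross-entropy loss, and is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from ._features import to_square_input

__all__ = [
    "ValveStateSequence",
    "FrameClassifierConfig",
    "FrameClassifier",
    "train_frame_classifier",
    "classify_frames",
    "select_es_frame",
    "frame_classification_metrics",
]

CLOSED_THRESHOLD = 0.5


@dataclass
class ValveStateSequence:
    """Per-frame probability and thresholded label of the closed valve state."""

    probabilities: np.ndarray
    labels: np.ndarray  # True = closed

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.array_equal(self.labels, self.probabilities >= CLOSED_THRESHOLD):
            raise ValueError("labels inconsistent with the 0.5 threshold")

    @classmethod
    def from_probabilities(cls, probabilities) -> "ValveStateSequence":
        p = np.asarray(probabilities, dtype=float)
        return cls(p, p >= CLOSED_THRESHOLD)

    @classmethod
    def from_labels(cls, labels) -> "ValveStateSequence":
        lab = np.asarray(labels, dtype=bool)
        return cls(lab.astype(float), lab)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FrameClassifierConfig:
    """Hyperparameters of the valve-state classifier.

    ``hidden_units`` is the per-layer width ladder of the MLP; frames are
    resampled to ``input_size`` x ``input_size`` with aspect-preserving
    padding before classification.
    """

    hidden_units: tuple[int, ...] = (64, 32)
    input_size: int = 32
    epochs: int = 300
    learning_rate: float = 0.01
    momentum: float = 0.9
    # intensity-jitter augmentation: each training frame is replicated with
    # additive Gaussian noise so the classifier tolerates acquisition noise
    augment_noise_sd: float = 0.02
    augment_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_units) < 1 or any(h <= 0 for h in self.hidden_units):
            raise ValueError("hidden_units must be a non-empty tuple of positive ints")
        for name in ("input_size", "epochs", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


class FrameClassifier:
    """Trained valve-state classifier with its preprocessing statistics."""

    def __init__(self, mlp: MLPClassifier, config: FrameClassifierConfig,
                 mean: np.ndarray, scale: np.ndarray):
        self.mlp = mlp
        self.config = config
        self.mean = mean
        self.scale = scale

    @property
    def initial_loss(self) -> float:
        return float(self.mlp.loss_curve_[0])

    @property
    def final_loss(self) -> float:
        return float(self.mlp.loss_curve_[-1])

    def _prepare(self, frames: Sequence[np.ndarray]) -> np.ndarray:
        size = self.config.input_size
        x = np.stack([to_square_input(f, size).ravel() for f in frames])
        return (x - self.mean) / self.scale

    def closed_probabilities(self, frames: Sequence[np.ndarray]) -> np.ndarray:
        x = self._prepare(frames)
        idx = list(self.mlp.classes_).index(1)
        return self.mlp.predict_proba(x)[:, idx]


def train_frame_classifier(
    studies: Iterable, config: FrameClassifierConfig | None = None
) -> FrameClassifier:
    """Train the valve-state classifier on labeled 4ch phantom frames.

    Every 4ch frame of every study contributes one training sample with its
    ground-truth valve state.  Raises when the training labels contain a
    single class (cross-entropy would be degenerate).
    """
    config = config or FrameClassifierConfig()
    frames: list[np.ndarray] = []
    labels: list[bool] = []
    for study in studies:
        states = np.asarray(study.truth_valve_states, dtype=bool)
        for frame, closed in zip(study.cine_4ch.frames, states):
            frames.append(frame)
            labels.append(bool(closed))
    if not frames:
        raise ValueError("empty training set")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single valve state")
    x = np.stack([to_square_input(f, config.input_size).ravel() for f in frames])
    if config.augment_noise_sd > 0 and config.augment_copies > 0:
        rng = np.random.default_rng(config.seed)
        jittered = [
            x + rng.normal(0.0, config.augment_noise_sd, size=x.shape)
            for _ in range(config.augment_copies)
        ]
        x = np.concatenate([x, *jittered])
        y = np.tile(y, config.augment_copies + 1)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale < 1e-8] = 1.0
    xs = (x - mean) / scale
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_units,
        solver="sgd",
        learning_rate_init=config.learning_rate,
        momentum=config.momentum,
        nesterovs_momentum=False,
        max_iter=config.epochs,
        random_state=config.seed,
        alpha=1e-3,
        tol=0.0,
        early_stopping=False,
    )
    mlp.fit(xs, y)
    return FrameClassifier(mlp, config, mean, scale)


def classify_frames(cine, model: FrameClassifier) -> ValveStateSequence:
    """Classify the valve state on every frame of a 4ch cine."""
    if cine.view_label != "4ch":
        raise ValueError(f"valve-state classification expects a 4ch cine, got {cine.view_label!r}")
    probs = model.closed_probabilities(cine.frames)
    return ValveStateSequence.from_probabilities(probs)


def _closed_runs(labels: np.ndarray, cyclic: bool) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of closed labels."""
    n = len(labels)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if labels[i]:
            j = i
            while j < n and labels[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    if cyclic and len(runs) >= 2 and labels[0] and labels[-1]:
        # merge the wrap-around pair: last run continues into the first
        first = runs.pop(0)
        start, length = runs.pop(-1)
        runs.append((start, length + first[1]))
    return runs


def select_es_frame(states: ValveStateSequence, cyclic: bool = False) -> int:
    """Last frame of the largest block of closed states.

    Runs are treated linearly by default (``cyclic=True`` merges a run that
    wraps from the last to the first frame).  Ties between equal-length runs
    are broken toward the earliest run.
    """
    labels = np.asarray(states.labels, dtype=bool)
    runs = _closed_runs(labels, cyclic)
    if not runs:
        raise ValueError("no ES detected: no closed valve state in the sequence")
    start, length = max(runs, key=lambda r: r[1])  # max is stable -> earliest
    return (start + length - 1) % len(labels)


def frame_classification_metrics(
    predicted: ValveStateSequence, truth
) -> tuple[float, float, float | None]:
    """(accuracy, recall, precision) with "closed" as the positive class.

    Precision is returned as None when there are no positive predictions.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted.labels, dtype=bool)
    if len(t) != len(p):
        raise ValueError("predicted and truth label sequences differ in length")
    tp = int(np.sum(p & t))
    accuracy = float(np.mean(p == t))
    recall = tp / int(t.sum()) if t.sum() else 1.0
    precision = tp / int(p.sum()) if p.sum() else None
    return accuracy, float(recall), precision
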