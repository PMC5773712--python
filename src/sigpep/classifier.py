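"""Feed-forward 220-50-2 classifier trained by backpropagation.

The network has sigmoidal hidden and output layers and is trained by
full-batch gradient descent on the mean squared error against one-hot
targets (secretory = (1, 0), non-secretory = (0, 1)).  The learning rate
adapts: after an epoch that reduces the loss it is multiplied by
``lr_up``; after an epoch that increases it the step is rejected (weights
restored) and the rate multiplied by ``lr_down``.  Training is fully
reproducible given the seed.

Feature columns are standardized (per-feature z-score, fitted on the
training set and stored in the model) before entering the network: the
encoder's factorial self-term spans many orders of magnitude, and raw
values saturate the sigmoids.  Standardization can be disabled via the
config.

Models serialize to a small versioned JSON document (shapes, weights,
scaler, hyperparameters) so they can be read outside Python.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

SECRETORY = "secretory"
NON_SECRETORY = "non_secretory"
LABELS = (SECRETORY, NON_SECRETORY)

MODEL_FORMAT = "sigpep-mlp"
MODEL_VERSION = 1


class TrainingError(RuntimeError):
    """Raised on invalid training input or numerical failure (NaN loss)."""


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the network and its training loop."""

    layer_sizes: Tuple[int, int, int] = (220, 50, 2)
    max_epochs: int = 300
    lr0: float = 0.5
    lr_up: float = 1.05
    lr_down: float = 0.7
    lr_min: float = 1e-8
    lr_max: float = 50.0
    tolerance: float = 1e-10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if any(n <= 0 for n in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not (0 < self.lr_down < 1 < self.lr_up):
            raise ValueError("need 0 < lr_down < 1 < lr_up")


@dataclass
class MLPModel:
    """Weights, biases and training log of a (possibly untrained) network."""

    config: MLPConfig
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    scaler_mean: Optional[np.ndarray] = None
    scaler_std: Optional[np.ndarray] = None
    #: per-epoch records: (epoch, loss, learning rate, step accepted).
    training_log: List[Tuple[int, float, float, bool]] = field(default_factory=list)

    def save(self, path) -> None:
        doc = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "layer_sizes": list(self.config.layer_sizes),
            "config": {
                "max_epochs": self.config.max_epochs,
                "lr0": self.config.lr0,
                "lr_up": self.config.lr_up,
                "lr_down": self.config.lr_down,
                "lr_min": self.config.lr_min,
                "lr_max": self.config.lr_max,
                "tolerance": self.config.tolerance,
                "seed": self.config.seed,
                "standardize": self.config.standardize,
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_std": None if self.scaler_std is None else self.scaler_std.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != MODEL_FORMAT:
            raise ValueError(f"not a {MODEL_FORMAT} file: {path}")
        if doc.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version {doc.get('version')}")
        config = MLPConfig(layer_sizes=tuple(doc["layer_sizes"]), **doc["config"])
        return cls(
            config=config,
            weights=[np.array(w) for w in doc["weights"]],
            biases=[np.array(b) for b in doc["biases"]],
            scaler_mean=None if doc["scaler_mean"] is None else np.array(doc["scaler_mean"]),
            scaler_std=None if doc["scaler_std"] is None else np.array(doc["scaler_std"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_model(config: MLPConfig) -> MLPModel:
    """Seeded uniform init in +/- 1/sqrt(fan-in)."""
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    sizes = config.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return MLPModel(config=config, weights=weights, biases=biases)


def _forward(model: MLPModel, X: np.ndarray):
    h = _sigmoid(X @ model.weights[0] + model.biases[0])
    y = _sigmoid(h @ model.weights[1] + model.biases[1])
    return h, y


def _targets(labels: Sequence[str]) -> np.ndarray:
    T = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        if lab == SECRETORY:
            T[i, 0] = 1.0
        elif lab == NON_SECRETORY:
            T[i, 1] = 1.0
        else:
            raise ValueError(f"unknown label: {lab!r}")
    return T


def _apply_scaler(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.scaler_mean is None:
        return X
    return (X - model.scaler_mean) / model.scaler_std


def train(features: np.ndarray, labels: Sequence[str], config: MLPConfig) -> MLPModel:
    """Train the network on an (n, 220) feature matrix with string labels.

    Raises
    ------
    TrainingError
        If only one class is present, feature width mismatches the input
        layer, or the loss becomes NaN (reported with its epoch index).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != config.layer_sizes[0]:
        raise TrainingError(
            f"features must be (n, {config.layer_sizes[0]}), got {X.shape}"
        )
    T = _targets(labels)
    if len(T) != len(X):
        raise TrainingError("features and labels length mismatch")
    n_pos = int(T[:, 0].sum())
    if n_pos == 0 or n_pos == len(T):
        raise TrainingError("training data must contain both classes")

    model = _init_model(config)
    if config.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        model.scaler_mean, model.scaler_std = mean, std
        X = (X - mean) / std

    n = len(X)
    lr = config.lr0
    _, y = _forward(model, X)
    loss = float(np.mean((y - T) ** 2))
    model.training_log.append((0, loss, lr, True))

    for epoch in range(1, config.max_epochs + 1):
        h, y = _forward(model, X)
        # Backprop of MSE through the two sigmoid layers.
        delta_out = (y - T) * y * (1.0 - y) * (2.0 / (n * 2))
        grad_w1 = h.T @ delta_out
        grad_b1 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ model.weights[1].T) * h * (1.0 - h)
        grad_w0 = X.T @ delta_hid
        grad_b0 = delta_hid.sum(axis=0)

        saved = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
        model.weights[0] -= lr * grad_w0
        model.biases[0] -= lr * grad_b0
        model.weights[1] -= lr * grad_w1
        model.biases[1] -= lr * grad_b1

        _, y_new = _forward(model, X)
        new_loss = float(np.mean((y_new - T) ** 2))
        if np.isnan(new_loss):
            raise TrainingError(f"loss became NaN at epoch {epoch}")

        if new_loss <= loss:
            accepted = True
            delta = loss - new_loss
            loss = new_loss
            lr = min(lr * config.lr_up, config.lr_max)
            model.training_log.append((epoch, loss, lr, True))
            if delta < config.tolerance:
                break
        else:
            # Reject the step: restore weights, shrink the rate.
            model.weights, model.biases = saved
            lr = lr * config.lr_down
            model.training_log.append((epoch, loss, lr, False))
            if lr < config.lr_min:
                break
    return model


def predict(model: MLPModel, features: np.ndarray) -> List[Tuple[str, float]]:
    """Classify each row; returns (label, secretory score in [0, 1]) per input.

    The label is the argmax of the two output units; an exact tie breaks
    toward non-secretory.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.config.layer_sizes[0]:
        raise ValueError(
            f"features must have {model.config.layer_sizes[0]} columns, got {X.shape[1]}"
        )
    X = _apply_scaler(model, X)
    _, y = _forward(model, X)
    out = []
    for row in y:
        label = SECRETORY if row[0] > row[1] else NON_SECRETORY
        out.append((label, float(row[0])))
    return out


def scores(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Secretory-unit outputs in [0, 1], usable directly as ROC scores."""
    return np.array([s for _, s in predict(model, features)])
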