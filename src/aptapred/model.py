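"""The MLP interaction classifier and reference baseline classifiers.

The network is a stack of seven fully connected layers (widths
configurable, final width 1), ReLU after every hidden layer, inverted
dropout behind each hidden layer during training, and a sigmoid output.
It is trained by minimizing binary cross-entropy with RMSprop (or plain
SGD), implemented directly on numpy so training is exactly reproducible
under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

DEFAULT_LAYER_SIZES = (256, 128, 64, 32, 16, 8, 1)


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the training schema."""


@dataclass
class MLPConfig:
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    dropout_rate: float = 0.3
    learning_rate: float = 0.00014
    batch_size: int = 5000
    epochs: int = 260
    optimizer: str = "rmsprop"
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) != 7:
            raise ValueError(
                f"layer_sizes must have exactly 7 entries, got {len(self.layer_sizes)}"
            )
        if self.layer_sizes[-1] != 1:
            raise ValueError("final layer width must be 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.optimizer not in ("rmsprop", "sgd"):
            raise ValueError(f"optimizer must be 'rmsprop' or 'sgd', got {self.optimizer!r}")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    p = np.clip(y_prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


class MLP:
    """Seven-layer dense network with dropout, trained by backprop."""

    def __init__(self, config: MLPConfig, n_inputs: int):
        if n_inputs < 1:
            raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
        self.config = config
        self.n_inputs = n_inputs
        self.feature_names: list[str] | None = None
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        rng = np.random.default_rng(config.seed)
        sizes = (n_inputs,) + config.layer_sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        """Returns (activations per layer, dropout masks, output probs)."""
        acts = [X]
        masks = []
        a = X
        n_layers = len(self.weights)
        rate = self.config.dropout_rate
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if i < n_layers - 1:
                a = relu(z)
                if training and rate > 0:
                    mask = (self._rng.random(a.shape) >= rate) / (1.0 - rate)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                a = sigmoid(z)
            acts.append(a)
        return acts, masks, a[:, 0]

    def _backward(self, acts, masks, y: np.ndarray):
        n = len(y)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        # output layer: d(BCE)/dz = (a - y) / n for sigmoid output
        delta = (acts[-1] - y[:, None]) / n
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_w, grads_b

    # -- training -----------------------------------------------------------

    def fit(self, X, y) -> "MLP":
        config = self.config
        Xa, names = _as_matrix(X)
        ya = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(Xa)):
            raise ValueError("training features contain non-finite values")
        if not set(np.unique(ya)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if Xa.shape[1] != self.n_inputs:
            raise SchemaError(f"expected {self.n_inputs} features, got {Xa.shape[1]}")
        self.feature_names = names

        n = len(Xa)
        batch = min(config.batch_size, n)
        cache_w = [np.zeros_like(W) for W in self.weights]
        cache_b = [np.zeros_like(b) for b in self.biases]
        rho, eps = 0.9, 1e-7
        lr = config.learning_rate

        for _ in range(config.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                acts, masks, _ = self._forward(Xa[idx], training=True)
                grads_w, grads_b = self._backward(acts, masks, ya[idx])
                for i in range(len(self.weights)):
                    if config.optimizer == "rmsprop":
                        cache_w[i] = rho * cache_w[i] + (1 - rho) * grads_w[i] ** 2
                        cache_b[i] = rho * cache_b[i] + (1 - rho) * grads_b[i] ** 2
                        self.weights[i] -= lr * grads_w[i] / (np.sqrt(cache_w[i]) + eps)
                        self.biases[i] -= lr * grads_b[i] / (np.sqrt(cache_b[i]) + eps)
                    else:
                        self.weights[i] -= lr * grads_w[i]
                        self.biases[i] -= lr * grads_b[i]
            probs = self._forward(Xa, training=False)[2]
            self.history["loss"].append(binary_cross_entropy(ya, probs))
            self.history["accuracy"].append(float(np.mean((probs >= 0.5) == ya)))
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        Xa, names = _as_matrix(X)
        if self.feature_names is not None and names is not None:
            if names != self.feature_names:
                missing = [c for c in self.feature_names if c not in names]
                extra = [c for c in names if c not in self.feature_names]
                raise SchemaError(
                    f"feature columns do not match training schema; "
                    f"missing={missing[:5]}, extra={extra[:5]}"
                )
        if Xa.shape[1] != self.n_inputs:
            raise SchemaError(f"expected {self.n_inputs} features, got {Xa.shape[1]}")
        return self._forward(Xa, training=False)[2]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        meta = {
            "config": asdict(self.config),
            "n_inputs": self.n_inputs,
            "feature_names": self.feature_names,
            "history": self.history,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MLP":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = meta["config"]
            cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
            model = cls(MLPConfig(**cfg), meta["n_inputs"])
            model.weights = [data[f"W{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
            model.feature_names = meta["feature_names"]
            model.history = meta["history"]
        return model


def build_mlp(config: MLPConfig, n_inputs: int) -> MLP:
    return MLP(config, n_inputs)


def train(model: MLP, X, y, config: MLPConfig | None = None) -> MLP:
    if config is not None:
        model.config = config
    return model.fit(X, y)


def predict_proba(model: MLP, X) -> np.ndarray:
    return model.predict_proba(X)


BASELINE_NAMES = ("knn", "rf", "svm", "snn")


def make_baseline(name: str, seed: int = 0):
    """The four reference classifiers with their fixed hyperparameters."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, leaf_size=25, p=2)
    if name == "rf":
        return RandomForestClassifier(max_depth=3, n_estimators=10, random_state=seed)
    if name == "svm":
        return SVC(
            degree=3, C=1, kernel="linear", probability=True,
            cache_size=200, random_state=seed,
        )
    if name == "snn":
        return MLPClassifier(
            hidden_layer_sizes=(3, 2), solver="lbfgs", alpha=0.0001,
            max_iter=2000, random_state=seed,
        )
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")


def baseline_fit_predict(name: str, X_train, y_train, X_test, seed: int = 0):
    """Fit a named baseline and return (probabilities, labels) on X_test."""
    clf = make_baseline(name, seed=seed)
    clf.fit(_as_matrix(X_train)[0], np.asarray(y_train))
    Xt = _as_matrix(X_test)[0]
    probs = clf.predict_proba(Xt)[:, list(clf.classes_).index(1)]
    return probs, clf.predict(Xt)


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.asarray(X, dtype=float), None
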