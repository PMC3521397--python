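"""A 21-8-5 feed-forward network with tanh activations, trained by online
backpropagation with momentum and RMSE-monitored early stopping.

Targets are coded +1 for the true class and -1 elsewhere to match the
tanh output range.  Inputs are z-scored with statistics of the training
split, stored with the model.  Prediction takes the argmax of the five
outputs and rejects to ``Unidentified`` when the maximum activation falls
below a threshold (debris and other foreign objects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

UNIDENTIFIED = "Unidentified"

DEFAULT_LABELS = ("Chroococcus", "Microcystis", "Navicula", "Oscillatoria", "Scenedesmus")


@dataclass
class MLPModel:
    """Network weights plus the standardizer and label map they assume."""

    w_hidden: np.ndarray           # (n_hidden, n_in)
    b_hidden: np.ndarray           # (n_hidden,)
    w_out: np.ndarray              # (n_out, n_hidden)
    b_out: np.ndarray              # (n_out,)
    label_map: tuple[str, ...] = DEFAULT_LABELS
    unknown_threshold: float = 0.5
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w_hidden.shape[1], self.w_hidden.shape[0], self.w_out.shape[0])

    def copy_weights(self):
        return (self.w_hidden.copy(), self.b_hidden.copy(),
                self.w_out.copy(), self.b_out.copy())

    def set_weights(self, weights):
        self.w_hidden, self.b_hidden, self.w_out, self.b_out = \
            (w.copy() for w in weights)

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "label_map": list(self.label_map),
            "unknown_threshold": self.unknown_threshold,
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_std": None if self.x_std is None else self.x_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            w_hidden=np.asarray(d["w_hidden"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            w_out=np.asarray(d["w_out"], dtype=float),
            b_out=np.asarray(d["b_out"], dtype=float),
            label_map=tuple(d["label_map"]),
            unknown_threshold=float(d["unknown_threshold"]),
            x_mean=None if d["x_mean"] is None else np.asarray(d["x_mean"], dtype=float),
            x_std=None if d["x_std"] is None else np.asarray(d["x_std"], dtype=float),
        )

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.05
    momentum: float = 0.05
    max_epochs: int = 400
    validation_fraction: float = 0.10
    seed: int = 0
    patience: int = 10

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if not (0 < self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5)")


@dataclass
class TrainingState:
    epoch: int = 0
    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    stopped_early: bool = False
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None


@dataclass
class TrainingSet:
    """Q feature rows (R = 21 columns) and +1/-1 coded targets (5 columns)."""

    features: np.ndarray
    targets: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError("features and targets must have equal row counts")
        if not np.all((self.targets == 1.0).sum(axis=1) == 1):
            raise ValueError("each target row must have exactly one +1")

    @classmethod
    def from_labels(cls, features: np.ndarray, labels: list[str],
                    label_map: tuple[str, ...] = DEFAULT_LABELS) -> "TrainingSet":
        idx = {name: i for i, name in enumerate(label_map)}
        targets = -np.ones((len(labels), len(label_map)))
        for r, lab in enumerate(labels):
            if lab not in idx:
                raise ValueError(f"label {lab!r} not in label map {label_map}")
            targets[r, idx[lab]] = 1.0
        return cls(features=np.asarray(features, dtype=float), targets=targets)


def init_mlp(seed: int, layer_sizes: tuple[int, int, int] = (21, 8, 5),
             label_map: tuple[str, ...] = DEFAULT_LABELS,
             unknown_threshold: float = 0.5) -> MLPModel:
    """Seeded initialization: weights uniform in [-1/sqrt(fan_in),
    +1/sqrt(fan_in)], biases zero."""
    rng = np.random.default_rng(seed)
    n_in, n_hidden, n_out = layer_sizes
    lim_h = 1.0 / np.sqrt(n_in)
    lim_o = 1.0 / np.sqrt(n_hidden)
    return MLPModel(
        w_hidden=rng.uniform(-lim_h, lim_h, size=(n_hidden, n_in)),
        b_hidden=np.zeros(n_hidden),
        w_out=rng.uniform(-lim_o, lim_o, size=(n_out, n_hidden)),
        b_out=np.zeros(n_out),
        label_map=label_map,
        unknown_threshold=unknown_threshold,
    )


def _standardize(model: MLPModel, x: np.ndarray) -> np.ndarray:
    if model.x_mean is None:
        return x
    return (x - model.x_mean) / model.x_std


def forward(model: MLPModel, x: np.ndarray, standardized: bool = True) -> np.ndarray:
    """h = tanh(W1 x + b1); y = tanh(W2 h + b2).

    ``standardized=False`` applies the model's stored z-scoring first.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.w_hidden.shape[1]:
        raise ValueError(f"expected input length {model.w_hidden.shape[1]}, got {x.shape[-1]}")
    if not standardized:
        x = _standardize(model, x)
    h = np.tanh(x @ model.w_hidden.T + model.b_hidden)
    return np.tanh(h @ model.w_out.T + model.b_out)


def _rmse(model: MLPModel, X: np.ndarray, T: np.ndarray) -> float:
    Y = forward(model, X)
    return float(np.sqrt(np.mean((Y - T) ** 2)))


def _stratified_split(targets: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class random split; every class keeps at least one training row."""
    classes = np.argmax(targets, axis=1)
    val_idx = []
    for c in np.unique(classes):
        members = np.flatnonzero(classes == c)
        if len(members) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples; cannot split")
        n_val = int(round(fraction * len(members)))
        n_val = min(max(n_val, 0), len(members) - 1)
        val_idx.extend(rng.permutation(members)[:n_val])
    val_mask = np.zeros(len(classes), dtype=bool)
    val_mask[val_idx] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def backprop_gradients(model: MLPModel, x: np.ndarray, t: np.ndarray):
    """Gradients of E = 1/2 * sum((y - t)^2) for a single presentation."""
    h = np.tanh(model.w_hidden @ x + model.b_hidden)
    y = np.tanh(model.w_out @ h + model.b_out)
    delta_out = (y - t) * (1.0 - y ** 2)
    delta_hidden = (model.w_out.T @ delta_out) * (1.0 - h ** 2)
    return (np.outer(delta_hidden, x), delta_hidden,
            np.outer(delta_out, h), delta_out)


def train(model: MLPModel, data: TrainingSet,
          cfg: TrainingConfig = TrainingConfig()) -> tuple[MLPModel, TrainingState]:
    """Online momentum backpropagation with early stopping.

    Per presentation: dw(t) = -lr * dE/dw + momentum * dw(t-1), with the
    presentation order reshuffled every epoch.  A stratified
    ``validation_fraction`` of the data is held out; training stops at
    ``max_epochs`` or once validation RMSE has risen for ``patience``
    consecutive epochs, and the best-validation weights are restored.
    """
    rng = np.random.default_rng(cfg.seed)
    state = TrainingState()
    if cfg.max_epochs == 0:
        return model, state

    X = data.features
    T = data.targets
    # z-score on the full training input; constant columns get sd 1
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    model.x_mean = mean
    model.x_std = std
    Xs = (X - mean) / std

    tr_idx, val_idx = _stratified_split(T, cfg.validation_fraction, rng)
    state.train_indices, state.val_indices = tr_idx, val_idx
    classes_present = np.unique(np.argmax(T, axis=1))
    if len(np.unique(np.argmax(T[tr_idx], axis=1))) < len(classes_present):
        raise ValueError("a class is absent from the training split")
    Xtr, Ttr = Xs[tr_idx], T[tr_idx]
    Xval, Tval = Xs[val_idx], T[val_idx]

    vel = [np.zeros_like(model.w_hidden), np.zeros_like(model.b_hidden),
           np.zeros_like(model.w_out), np.zeros_like(model.b_out)]
    best_val = np.inf
    best_weights = model.copy_weights()
    rising = 0
    prev_val = np.inf

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        for i in order:
            grads = backprop_gradients(model, Xtr[i], Ttr[i])
            params = [model.w_hidden, model.b_hidden, model.w_out, model.b_out]
            for p, g, v in zip(params, grads, vel):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                p += v
        state.epoch = epoch + 1
        state.train_rmse.append(_rmse(model, Xtr, Ttr))
        val = _rmse(model, Xval, Tval) if len(Xval) else state.train_rmse[-1]
        state.val_rmse.append(val)
        if val < best_val:
            best_val = val
            best_weights = model.copy_weights()
        rising = rising + 1 if val > prev_val else 0
        prev_val = val
        if rising >= cfg.patience:
            state.stopped_early = True
            break

    model.set_weights(best_weights)
    return model, state


def predict(model: MLPModel, x: np.ndarray, standardized: bool = False) -> str:
    """Class label of a single feature vector, or ``Unidentified`` when the
    maximum activation is below the rejection threshold (ties -> lowest
    output index)."""
    y = forward(model, np.asarray(x, dtype=float), standardized=standardized)
    best = int(np.argmax(y))
    if y[best] < model.unknown_threshold:
        return UNIDENTIFIED
    return model.label_map[best]


def predict_batch(model: MLPModel, X: np.ndarray, standardized: bool = False) -> list[str]:
    return [predict(model, x, standardized=standardized) for x in np.atleast_2d(X)]


def evaluate(preds: list[str], truth: list[str],
             label_map: tuple[str, ...] = DEFAULT_LABELS):
    """Confusion matrix over the 5 genera plus the Unidentified column.

    Rows are true labels, columns predictions, both ordered
    ``label_map + (Unidentified,)``; true labels outside the map fall in the
    Unidentified row.  Per-class accuracy is diagonal over row sum; overall
    accuracy is the diagonal sum over N (rejections of true genera count as
    errors).
    """
    if len(preds) != len(truth):
        raise ValueError("prediction and truth lists must have equal length")
    names = list(label_map) + [UNIDENTIFIED]
    index = {n: i for i, n in enumerate(names)}
    matrix = np.zeros((len(names), len(names)), dtype=int)
    for p, t in zip(preds, truth):
        if p not in index:
            raise ValueError(f"prediction label {p!r} outside the label map")
        ti = index.get(t, index[UNIDENTIFIED])
        matrix[ti, index[p]] += 1
    row_sums = matrix.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(row_sums > 0, np.diag(matrix) / np.maximum(row_sums, 1), np.nan)
    overall = float(np.trace(matrix) / len(preds)) if preds else float("nan")
    return {
        "labels": names,
        "matrix": matrix,
        "per_class_accuracy": {n: float(per_class[i]) for i, n in enumerate(names) if row_sums[i] > 0},
        "overall_accuracy": overall,
    }
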