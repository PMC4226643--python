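"""One-hidden-layer sigmoid perceptron trained by online backpropagation.

The network maps the 15 standardized descriptors through a hidden layer of
``h`` sigmoid units to ``m`` sigmoid outputs (one per species).  Training
is plain stochastic gradient descent on the squared error

    E = 1/2 * sum_i (y_i - t_i)^2

with one weight update per pattern presentation ("generation"); patterns
are drawn cyclically in a freshly shuffled order each pass.  Weights and
biases start uniform in (-0.5, 0.5) from the given seed, so training is
bit-reproducible.

Features are z-scored with the training-set mean and standard deviation;
the scaler is stored in the model and applied at prediction time (raw
descriptors span many orders of magnitude — pixel areas next to
probabilities — and a sigmoid net cannot train on them unscaled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES, LABEL_COLUMN

__all__ = ["TrainConfig", "MLPModel", "Prediction", "sigmoid", "train",
           "predict", "predict_batch", "save_model", "load_model"]

MODEL_FORMAT_VERSION = 1


def sigmoid(x):
    """Logistic activation 1 / (1 + exp(-x)); saturates without overflow."""
    x = np.asarray(x, np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    learning_rate
        SGD step size (0 < lr <= 1).
    generations
        Total number of pattern presentations (not epochs).
    hidden
        Hidden-layer width h.
    seed
        RNG seed for weight init and presentation order.
    train_fraction
        Default train/test split proportion used by the evaluation
        protocol.
    momentum
        Classical momentum coefficient (0 = plain gradient descent).
    """

    learning_rate: float = 0.1
    generations: int = 50_000
    hidden: int = 60
    seed: int = 0
    train_fraction: float = 0.8
    momentum: float = 0.0

    def __post_init__(self):
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class MLPModel:
    """Fitted network: weights, feature scaler, label map and the config
    that produced it.  ``loss_trace`` holds the per-presentation squared
    error (useful for convergence diagnostics)."""

    w_hidden: np.ndarray   # (n_features, h)
    b_hidden: np.ndarray   # (h,)
    w_out: np.ndarray      # (h, m)
    b_out: np.ndarray      # (m,)
    labels: list
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: TrainConfig
    loss_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def hidden(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_species(self) -> int:
        return self.w_out.shape[1]


@dataclass(frozen=True)
class Prediction:
    """Outcome for one pattern: winning species (argmax of the raw sigmoid
    outputs, ties to the lowest index), the raw outputs, the thresholded
    binary outputs (step at 0.5) and whether any output cleared 0.5."""

    species: object
    raw: np.ndarray
    binary: np.ndarray
    confident: bool


def _forward(x, w1, b1, w2, b2):
    a1 = sigmoid(x @ w1 + b1)
    y = sigmoid(a1 @ w2 + b2)
    return a1, y


def _gradients(x, t, w1, b1, w2, b2):
    """Loss 1/2||y - t||^2 and its gradients for one pattern (analytic
    backpropagation; checked against finite differences in the tests)."""
    a1, y = _forward(x, w1, b1, w2, b2)
    err = y - t
    loss = 0.5 * float(err @ err)
    d_out = err * y * (1.0 - y)
    d_hid = (w2 @ d_out) * a1 * (1.0 - a1)
    return loss, np.outer(x, d_hid), d_hid, np.outer(a1, d_out), d_out


def _standardize_fit(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: leave centered at 0
    return mean, sd


def train(table, config: TrainConfig = TrainConfig()) -> MLPModel:
    """Fit the perceptron to a feature table (DataFrame with the 15 feature
    columns plus a species column)."""
    X = np.asarray(table[FEATURE_NAMES], np.float64)
    if not np.all(np.isfinite(X)):
        row = int(np.nonzero(~np.isfinite(X).all(axis=1))[0][0])
        raise ValueError(f"non-finite feature in row {row}")
    labels_col = list(table[LABEL_COLUMN])
    labels = sorted(set(labels_col))
    if len(labels) < 2:
        raise ValueError("training requires at least 2 species")
    index = {s: i for i, s in enumerate(labels)}
    t_idx = np.array([index[s] for s in labels_col])
    n, n_feat = X.shape
    m = len(labels)

    mean, sd = _standardize_fit(X)
    Z = (X - mean) / sd
    T = np.zeros((n, m))
    T[np.arange(n), t_idx] = 1.0

    rng = np.random.default_rng(config.seed)
    h = config.hidden
    w1 = rng.uniform(-0.5, 0.5, (n_feat, h))
    b1 = rng.uniform(-0.5, 0.5, h)
    w2 = rng.uniform(-0.5, 0.5, (h, m))
    b2 = rng.uniform(-0.5, 0.5, m)
    v1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    v2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)

    lr, mom = config.learning_rate, config.momentum
    order = rng.permutation(n)
    pos = 0
    trace = np.empty(config.generations)
    for g in range(config.generations):
        if pos == n:
            order = rng.permutation(n)
            pos = 0
        i = order[pos]
        pos += 1
        loss, gw1, gb1, gw2, gb2 = _gradients(Z[i], T[i], w1, b1, w2, b2)
        trace[g] = loss
        if mom:
            v1 = mom * v1 - lr * gw1; vb1 = mom * vb1 - lr * gb1
            v2 = mom * v2 - lr * gw2; vb2 = mom * vb2 - lr * gb2
            w1 += v1; b1 += vb1; w2 += v2; b2 += vb2
        else:
            w1 -= lr * gw1; b1 -= lr * gb1
            w2 -= lr * gw2; b2 -= lr * gb2

    return MLPModel(w_hidden=w1, b_hidden=b1, w_out=w2, b_out=b2,
                    labels=labels, scaler_mean=mean, scaler_sd=sd,
                    config=config, loss_trace=trace)


def _raw_outputs(model: MLPModel, X: np.ndarray) -> np.ndarray:
    Z = (X - model.scaler_mean) / model.scaler_sd
    a1 = sigmoid(Z @ model.w_hidden + model.b_hidden)
    return sigmoid(a1 @ model.w_out + model.b_out)


def predict(model: MLPModel, fv) -> Prediction:
    """Classify one 15-vector of descriptors."""
    fv = np.asarray(fv, np.float64)
    if fv.shape != (model.n_features,):
        raise ValueError(
            f"feature vector has shape {fv.shape}, model expects "
            f"({model.n_features},)")
    if not np.all(np.isfinite(fv)):
        raise ValueError("non-finite feature vector")
    raw = _raw_outputs(model, fv[None, :])[0]
    k = int(np.argmax(raw))
    binary = (raw >= 0.5).astype(int)
    return Prediction(species=model.labels[k], raw=raw, binary=binary,
                      confident=bool(binary.any()))


def predict_batch(model: MLPModel, X) -> list:
    """Winning species for each row of a feature matrix or table."""
    if hasattr(X, "columns"):
        X = np.asarray(X[FEATURE_NAMES], np.float64)
    X = np.asarray(X, np.float64)
    raw = _raw_outputs(model, X)
    return [model.labels[int(k)] for k in np.argmax(raw, axis=1)]


def save_model(model: MLPModel, path) -> None:
    """Serialize to a single JSON container (weights, scaler, label map,
    config and a format-version field)."""
    payload = {
        "format": "taxofeat-mlp",
        "version": MODEL_FORMAT_VERSION,
        "labels": list(model.labels),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out.tolist(),
        "config": asdict(model.config),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> MLPModel:
    data = json.loads(Path(path).read_text())
    if data.get("format") != "taxofeat-mlp":
        raise ValueError(f"{path} is not a taxofeat model file")
    return MLPModel(
        w_hidden=np.array(data["w_hidden"]),
        b_hidden=np.array(data["b_hidden"]),
        w_out=np.array(data["w_out"]),
        b_out=np.array(data["b_out"]),
        labels=data["labels"],
        scaler_mean=np.array(data["scaler_mean"]),
        scaler_sd=np.array(data["scaler_sd"]),
        config=TrainConfig(**data["config"]),
    )
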