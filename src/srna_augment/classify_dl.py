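"""Fully connected classifier with a transparent forward pass.

A small numpy implementation of a dense network (ReLU hidden layers,
softmax output, inverted dropout, Adam, cross-entropy) whose forward
pass can return every layer's pre-activations and activations — the
contract the attribution module depends on.  Default architecture:
three hidden layers of 1000/250/250 units with dropout 0.5/0.4/0.4,
trained 50 epochs with batch size 30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DenseNetModel", "TrainConfig", "build_network", "train",
           "predict_proba", "predict", "save_model", "load_model"]

ADAM_DEFAULTS = {"lr": 1e-3, "beta1": 0.9, "beta2": 0.999, "eps": 1e-8}


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 30
    lr: float = ADAM_DEFAULTS["lr"]
    beta1: float = ADAM_DEFAULTS["beta1"]
    beta2: float = ADAM_DEFAULTS["beta2"]
    eps: float = ADAM_DEFAULTS["eps"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class DenseNetModel:
    """Weights, biases and dropout rates of the dense classifier.

    ``weights[l]`` has shape (fan_in, fan_out); hidden layers use ReLU,
    the output layer softmax.  ``classes_`` maps output indices back to
    the original labels.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout: list[float]
    classes_: np.ndarray
    loss_name: str = "categorical_cross_entropy"
    history: list[float] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]

    def forward(
        self,
        X: np.ndarray,
        *,
        return_internals: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Forward pass.

        Returns softmax probabilities; with ``return_internals`` also a
        list of (pre_activation, activation) pairs per layer, where the
        final pair holds (logits, probabilities).  Dropout is applied
        only when ``dropout_rng`` is supplied (training).
        """
        X = np.asarray(X)
        if X.dtype not in (np.float32, np.float64):
            X = X.astype(np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"input width {X.shape[1]} != model n_inputs {self.n_inputs}"
            )
        a = X
        internals = []
        masks = []
        last = self.n_layers - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if l == last:
                act = _softmax(z)
            else:
                act = np.maximum(z, 0.0)
                if dropout_rng is not None and self.dropout[l] > 0:
                    keep = 1.0 - self.dropout[l]
                    mask = ((dropout_rng.random(act.shape) < keep) / keep).astype(act.dtype)
                    act = act * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            internals.append((z, act))
            a = act
        if return_internals:
            return a, internals, masks
        return a

    def logits(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax output (attribution target)."""
        _, internals, _ = self.forward(X, return_internals=True)
        return internals[-1][0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(
    n_inputs: int,
    n_classes: int,
    hidden: list[int] | None = None,
    dropout: list[float] | None = None,
    seed: int = 0,
    classes: np.ndarray | None = None,
) -> DenseNetModel:
    """Initialize a dense network with Glorot-uniform weights.

    ``hidden=[]`` yields a single softmax layer (multinomial logistic
    regression).
    """
    if hidden is None:
        hidden = [1000, 250, 250]
    if dropout is None:
        dropout = [0.5, 0.4, 0.4][: len(hidden)] + [0.0] * max(0, len(hidden) - 3)
    if len(hidden) != len(dropout):
        raise ValueError("hidden and dropout must have equal length")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    dims = [n_inputs] + list(hidden) + [n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    if classes is None:
        classes = np.arange(n_classes)
    classes = np.asarray(classes)
    if len(classes) != n_classes:
        raise ValueError("classes length must equal n_classes")
    loss = "binary_cross_entropy" if n_classes == 2 else "categorical_cross_entropy"
    return DenseNetModel(
        weights=weights,
        biases=biases,
        dropout=list(dropout),
        classes_=classes,
        loss_name=loss,
    )


def train(
    model: DenseNetModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> DenseNetModel:
    """Train in place with Adam on cross-entropy; returns the model.

    Binary cross-entropy applies when there are two classes, categorical
    otherwise (with a 2-unit softmax the two coincide).  Batch order and
    dropout masks are drawn from ``cfg.seed`` so training is
    deterministic.  Per-epoch mean losses are appended to
    ``model.history``.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    class_to_idx = {c: i for i, c in enumerate(model.classes_)}
    try:
        y_idx = np.array([class_to_idx[v] for v in y])
    except KeyError as e:
        raise ValueError(f"label {e} not in model classes") from None
    onehot = np.eye(model.n_classes, dtype=np.float32)[y_idx]

    # float32 during optimization (Adam's elementwise updates dominate the
    # runtime); weights are widened back to float64 afterwards so the
    # attribution path works in double precision.
    model.weights = [W.astype(np.float32) for W in model.weights]
    model.biases = [b.astype(np.float32) for b in model.biases]

    rng = np.random.default_rng(cfg.seed)
    params = model.weights + model.biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    scratch = [np.empty_like(p) for p in params]
    one_m_b1 = np.float32(1 - cfg.beta1)
    b1 = np.float32(cfg.beta1)
    b2 = np.float32(cfg.beta2)
    one_m_b2 = np.float32(1 - cfg.beta2)
    eps = np.float32(cfg.eps)

    t = 0
    n = X.shape[0]
    L = model.n_layers
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], onehot[idx]
            probs, internals, masks = model.forward(
                xb, return_internals=True, dropout_rng=rng
            )
            loss = -np.mean(np.sum(yb * np.log(np.clip(probs, 1e-12, None)), axis=1))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at step {t}: {loss}"
                )
            epoch_losses.append(float(loss))
            # softmax + cross-entropy gradient
            delta = (probs - yb) / np.float32(len(idx))
            grads: list = [None] * (2 * L)
            for l in range(L - 1, -1, -1):
                a_prev = xb if l == 0 else internals[l - 1][1]
                grads[l] = a_prev.T @ delta
                grads[L + l] = delta.sum(axis=0)
                if l > 0:
                    z_prev = internals[l - 1][0]
                    delta = delta @ model.weights[l].T
                    if masks[l - 1] is not None:
                        delta *= masks[l - 1]
                    delta *= z_prev > 0
            t += 1
            # bias-corrected step size folded into one scalar
            alpha = np.float32(
                cfg.lr * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
            )
            for p, g, m_s, v_s, tmp in zip(params, grads, m_state, v_state, scratch):
                m_s *= b1
                np.multiply(g, one_m_b1, out=tmp)
                m_s += tmp
                np.multiply(g, g, out=tmp)
                tmp *= one_m_b2
                v_s *= b2
                v_s += tmp
                np.sqrt(v_s, out=tmp)
                tmp += eps
                np.divide(m_s, tmp, out=tmp)
                tmp *= alpha
                p -= tmp
        model.history.append(float(np.mean(epoch_losses)))

    model.weights = [W.astype(np.float64) for W in model.weights]
    model.biases = [b.astype(np.float64) for b in model.biases]
    return model


def predict_proba(model: DenseNetModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities (dropout disabled); rows sum to 1."""
    return model.forward(X)


def predict(model: DenseNetModel, X: np.ndarray) -> np.ndarray:
    """Labels by argmax probability; ties break to the lowest class index."""
    probs = predict_proba(model, X)
    return model.classes_[np.argmax(probs, axis=1)]


def save_model(model: DenseNetModel, path: str | Path) -> None:
    """Serialize weights + architecture + label encoding to one .npz file."""
    path = Path(path)
    meta = {
        "dropout": model.dropout,
        "loss_name": model.loss_name,
        "classes": [_jsonable(c) for c in model.classes_],
        "history": model.history,
        "n_layers": model.n_layers,
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def _jsonable(v):
    return v.item() if isinstance(v, np.generic) else v


def load_model(path: str | Path) -> DenseNetModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"W{i}"] for i in range(meta["n_layers"])]
        biases = [data[f"b{i}"] for i in range(meta["n_layers"])]
    return DenseNetModel(
        weights=weights,
        biases=biases,
        dropout=meta["dropout"],
        classes_=np.array(meta["classes"]),
        loss_name=meta["loss_name"],
        history=meta["history"],
    )
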