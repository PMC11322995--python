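"""Networks, residual composition, losses, optimizers and the fit loop."""

from __future__ import annotations

import numpy as np

from .layers import Dropout, GroupedConv2D, Layer

__all__ = [
    "Sequential",
    "ResidualBlock",
    "Adam",
    "SGD",
    "TrainingDivergedError",
    "cross_entropy",
    "cross_entropy_grad",
    "fit_network",
]


class Sequential(Layer):
    """An ordered stack of layers; itself usable as a layer."""

    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = list(layers)
        self.name = name

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        """Depth-first iteration over leaf layers."""
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock)):
                yield from layer.iter_layers()
            else:
                yield layer

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.iter_layers():
            if isinstance(layer, Dropout):
                layer.rng = rng


class ResidualBlock(Layer):
    """Main path plus a skip connection added to its output.

    The skip is the identity when channel counts match, a 1x1 grouped
    projection when they do not, or absent (``skip=False``) for the
    no-shortcut ablation.
    """

    def __init__(
        self,
        main: Sequential,
        projection: GroupedConv2D | None = None,
        skip: bool = True,
        name: str = "residual_block",
    ):
        self.main = main
        self.projection = projection
        self.skip = skip
        self.name = name

    @property
    def params(self):
        p = list(self.main.params)
        if self.projection is not None:
            p += self.projection.params
        return p

    @property
    def grads(self):
        g = list(self.main.grads)
        if self.projection is not None:
            g += self.projection.grads
        return g

    def iter_layers(self):
        yield from self.main.iter_layers()
        if self.projection is not None:
            yield self.projection

    def forward(self, x, training=False):
        out = self.main.forward(x, training=training)
        if not self.skip:
            return out
        if self.projection is not None:
            return out + self.projection.forward(x, training=training)
        return out + x

    def backward(self, dy):
        dx = self.main.backward(dy)
        if not self.skip:
            return dx
        if self.projection is not None:
            return dx + self.projection.backward(dy)
        return dx + dy


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

_PROB_FLOOR = 1e-12


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy in nats, probabilities clipped."""
    p = np.clip(probs[np.arange(len(labels)), labels], _PROB_FLOOR, 1.0)
    return float(-np.log(p).mean())


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy w.r.t. the probability matrix."""
    n = len(labels)
    g = np.zeros_like(probs, dtype=np.float32)
    idx = np.arange(n)
    p = np.clip(probs[idx, labels], _PROB_FLOOR, 1.0)
    g[idx, labels] = -1.0 / (n * p)
    return g


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params, grads, learning_rate=1e-2, momentum=0.9):
        self.params = params
        self.grads = grads
        self.lr = learning_rate
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(
        self, params, grads, learning_rate=1e-3, beta1=0.9, beta2=0.999, eps=1e-8
    ):
        self.params = params
        self.grads = grads
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


_OPTIMIZERS = {"adam": Adam, "sgd": SGD}


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN/inf."""


def fit_network(
    net,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    *,
    optimizer: str = "adam",
    learning_rate: float = 1e-3,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
    early_stop_patience: int | None = None,
) -> list[dict]:
    """Minimize cross-entropy by mini-batch gradient descent.

    ``net`` must expose forward/backward/params/grads and produce class
    probabilities.  Returns the per-epoch history as a list of dicts with
    train_loss, train_accuracy, val_loss, val_accuracy (val entries are
    None when no validation set is given).  Deterministic for a fixed
    seed on a fixed BLAS configuration.
    """
    if optimizer not in _OPTIMIZERS:
        raise ValueError(f"optimizer must be one of {sorted(_OPTIMIZERS)}")
    if epochs < 1 or batch_size < 1 or learning_rate <= 0:
        raise ValueError("epochs/batch_size must be >= 1 and learning_rate > 0")
    X_train = np.ascontiguousarray(X_train, dtype=np.float32)
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(seed)
    if hasattr(net, "set_dropout_rng"):
        net.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    opt = _OPTIMIZERS[optimizer](net.params, net.grads, learning_rate)
    n = len(X_train)
    history: list[dict] = []
    best_val, since_best = np.inf, 0
    for _epoch in range(epochs):
        perm = rng.permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = X_train[idx], y_train[idx]
            probs = net.forward(xb, training=True)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {_epoch}, "
                    f"batch starting {start}; last lr={learning_rate}"
                )
            net.backward(cross_entropy_grad(probs, yb))
            opt.step()
            tot_loss += loss * len(idx)
            tot_correct += int((probs.argmax(axis=1) == yb).sum())
        rec = {
            "train_loss": tot_loss / n,
            "train_accuracy": tot_correct / n,
            "val_loss": None,
            "val_accuracy": None,
        }
        if X_val is not None and len(X_val):
            vp = predict_proba(net, X_val, batch_size=max(batch_size, 256))
            rec["val_loss"] = cross_entropy(vp, y_val)
            rec["val_accuracy"] = float((vp.argmax(axis=1) == y_val).mean())
        history.append(rec)
        if early_stop_patience is not None and rec["val_loss"] is not None:
            if rec["val_loss"] < best_val - 1e-6:
                best_val, since_best = rec["val_loss"], 0
            else:
                since_best += 1
                if since_best >= early_stop_patience:
                    break
    return history


def predict_proba(net, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Forward pass in inference mode (dropout off, BN running stats)."""
    X = np.ascontiguousarray(X, dtype=np.float32)
    chunks = [
        net.forward(X[i : i + batch_size], training=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(chunks, axis=0)
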