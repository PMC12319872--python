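"""One-dimensional shallow convolutional network (1D-SCNN), in NumPy.

The network maps a 32-channel x 27-frequency periodic-power matrix to
two class probabilities:

    conv(kernel 7, 25 filters, stride 1, valid) -> ReLU
    -> conv(kernel 5, 20 filters, stride 1, valid) -> ReLU
    -> global average pooling -> dropout(0.1)
    -> fully connected (2) -> softmax

Electrodes are the input channels and frequency is the convolution
axis, so the sequence length shrinks 27 -> 21 -> 17. Training minimizes
two-class cross-entropy with Adam (lr 1e-4, batch 100, up to 100
epochs), monitoring a validation set with early stopping (patience 10,
best weights restored). All randomness (He initialization, batch
shuffling, dropout) flows from one seed, so training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScnnConfig:
    """Architecture and training hyperparameters (defaults as cited)."""

    conv1_filters: int = 25
    conv1_kernel: int = 7
    conv2_filters: int = 20
    conv2_kernel: int = 5
    dropout_p: float = 0.1
    n_classes: int = 2
    learning_rate: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 100
    patience: int = 10

    def __post_init__(self):
        for name in ("conv1_filters", "conv1_kernel", "conv2_filters",
                     "conv2_kernel", "n_classes", "max_epochs",
                     "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) -> (N, L-k+1, C*k) sliding patches."""
    win = np.lib.stride_tricks.sliding_window_view(X, k, axis=2)
    # win: (N, C, Lo, k) -> (N, Lo, C, k)
    n, c, lo, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(n, lo, c * k)


def _conv_forward(X, W, b, k):
    """W: (C*k, F); returns (N, F, Lo) and the patch cache."""
    P = _im2col(X, k)
    Y = P @ W + b  # (N, Lo, F)
    return Y.transpose(0, 2, 1), P


def _conv_backward(dY, P, W, x_shape, k):
    """Gradients of a valid 1-D convolution."""
    n, c, L = x_shape
    dYr = dY.transpose(0, 2, 1)  # (N, Lo, F)
    lo = dYr.shape[1]
    dW = np.tensordot(P, dYr, axes=([0, 1], [0, 1]))  # (C*k, F)
    db = dYr.sum(axis=(0, 1))
    dP = dYr @ W.T  # (N, Lo, C*k)
    dP = dP.reshape(n, lo, c, k)
    dX = np.zeros(x_shape)
    for j in range(k):
        dX[:, :, j:j + lo] += dP[:, :, :, j].transpose(0, 2, 1)
    return dX, dW, db


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ShallowCNN:
    """The 1D-SCNN estimator: ``fit`` / ``predict_proba`` / ``predict``."""

    def __init__(self, config: ScnnConfig = ScnnConfig(),
                 n_channels: int = 32, n_freqs: int = 27, seed=None):
        self.config = config
        self.n_channels = n_channels
        self.n_freqs = n_freqs
        lo1 = n_freqs - config.conv1_kernel + 1
        lo2 = lo1 - config.conv2_kernel + 1
        if lo2 < 1:
            raise ValueError("input too short for the two valid convolutions")
        self.seq_lengths = (n_freqs, lo1, lo2)
        self._rng = np.random.default_rng(seed)
        self._init_params()
        self._opt_state = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- parameters ---------------------------------------------------------
    def _init_params(self):
        cfg = self.config
        rng = self._rng

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        c1_in = self.n_channels * cfg.conv1_kernel
        c2_in = cfg.conv1_filters * cfg.conv2_kernel
        self.params = {
            "W1": he(c1_in, (c1_in, cfg.conv1_filters)),
            "b1": np.zeros(cfg.conv1_filters),
            "W2": he(c2_in, (c2_in, cfg.conv2_filters)),
            "b2": np.zeros(cfg.conv2_filters),
            "W3": he(cfg.conv2_filters, (cfg.conv2_filters, cfg.n_classes)),
            "b3": np.zeros(cfg.n_classes),
        }

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, train=False):
        cfg = self.config
        p = self.params
        cache = {"X": X}
        Z1, P1 = _conv_forward(X, p["W1"], p["b1"], cfg.conv1_kernel)
        A1 = np.maximum(Z1, 0.0)
        Z2, P2 = _conv_forward(A1, p["W2"], p["b2"], cfg.conv2_kernel)
        A2 = np.maximum(Z2, 0.0)
        G = A2.mean(axis=2)  # global average pool -> (N, F2)
        if train and cfg.dropout_p > 0:
            mask = (self._rng.random(G.shape) >= cfg.dropout_p)
            G = G * mask / (1.0 - cfg.dropout_p)
            cache["drop_mask"] = mask
        logits = G @ p["W3"] + p["b3"]
        probs = _softmax(logits)
        cache.update(P1=P1, Z1=Z1, A1=A1, P2=P2, Z2=Z2, A2=A2, G=G, probs=probs)
        return probs, cache

    def _backward(self, y, cache):
        cfg = self.config
        p = self.params
        n = len(y)
        dlogits = cache["probs"].copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "W3": cache["G"].T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dG = dlogits @ p["W3"].T
        if "drop_mask" in cache:
            dG = dG * cache["drop_mask"] / (1.0 - cfg.dropout_p)
        lo2 = self.seq_lengths[2]
        dA2 = np.repeat(dG[:, :, None] / lo2, lo2, axis=2)
        dZ2 = dA2 * (cache["Z2"] > 0)
        dA1, grads["W2"], grads["b2"] = _conv_backward(
            dZ2, cache["P2"], p["W2"], cache["A1"].shape, cfg.conv2_kernel)
        dZ1 = dA1 * (cache["Z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(
            dZ1, cache["P1"], p["W1"], cache["X"].shape, cfg.conv1_kernel)
        return grads

    @staticmethod
    def _cross_entropy(probs, y):
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def _adam_step(self, grads):
        lr = self.config.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        if self._opt_state is None:
            self._opt_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._opt_state
        st["t"] += 1
        t = st["t"]
        for k, g in grads.items():
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * g
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * g * g
            mhat = st["m"][k] / (1 - beta1 ** t)
            vhat = st["v"][k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training -----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam and early stopping.

        X is (n, n_channels, n_freqs); y is 0/1. When a validation set
        is given, its loss is monitored (patience epochs without
        improvement stops training and the best weights are restored);
        otherwise training loss is monitored the same way.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim == 2:
            X = X.reshape(len(X), self.n_channels, self.n_freqs)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        use_val = X_val is not None and len(X_val) > 0
        if use_val:
            X_val = np.asarray(X_val, dtype=float)
            if X_val.ndim == 2:
                X_val = X_val.reshape(len(X_val), self.n_channels, self.n_freqs)
            y_val = np.asarray(y_val).astype(int)
        cfg = self.config
        best_loss = np.inf
        best_params = None
        stall = 0
        n = len(X)
        for _epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                probs, cache = self._forward(X[idx], train=True)
                epoch_loss += self._cross_entropy(probs, y[idx]) * len(idx)
                self._adam_step(self._backward(y[idx], cache))
            train_loss = epoch_loss / n
            self.history["train_loss"].append(train_loss)
            if use_val:
                val_probs, _ = self._forward(X_val, train=False)
                monitor = self._cross_entropy(val_probs, y_val)
                self.history["val_loss"].append(monitor)
            else:
                monitor = train_loss
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(len(X), self.n_channels, self.n_freqs)
        probs, _ = self._forward(X, train=False)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def clone_with_seed(self, seed) -> "ShallowCNN":
        """Fresh, untrained copy of this architecture."""
        return ShallowCNN(self.config, self.n_channels, self.n_freqs, seed)

    def copy(self) -> "ShallowCNN":
        """Deep copy of the trained network (optimizer state reset), for
        fine-tuning without disturbing the original."""
        out = ShallowCNN(self.config, self.n_channels, self.n_freqs)
        out.params = {k: v.copy() for k, v in self.params.items()}
        out._rng = np.random.default_rng(self._rng.bit_generator.state["state"]["state"] % (2**63))
        return out


def build_scnn(config: ScnnConfig = ScnnConfig(), n_channels: int = 32,
               n_freqs: int = 27, seed=None) -> ShallowCNN:
    """Construct an untrained 1D-SCNN."""
    return ShallowCNN(config, n_channels, n_freqs, seed)


def train_scnn(model: ShallowCNN, train: tuple[np.ndarray, np.ndarray],
               validation: tuple[np.ndarray, np.ndarray] | None = None,
               ) -> ShallowCNN:
    """Train a built model on (X, y), monitoring a validation pair."""
    X, y = train
    if validation is not None:
        return model.fit(X, y, validation[0], validation[1])
    return model.fit(X, y)
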