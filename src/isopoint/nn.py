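"""Minimal feed-forward / separable-convolution network with Adam and MSE.

A compact, fully seeded numpy implementation of the handful of layer types
the package's trainable models need: dense layers with selu/elu/relu
activations, inverted dropout, depthwise-separable 2D convolution, average
pooling and flattening, trained by mini-batch Adam on a mean-squared-error
loss with a held-out validation split and early stopping (best weights
restored).

Shapes follow the channels-last convention: batches are ``(N, H, W, C)``
for convolutional input and ``(N, D)`` for dense input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _activation(name: str) -> tuple[Callable, Callable]:
    """Return (forward, derivative-given-preactivation) for an activation."""
    if name == "linear":
        return (lambda z: z, lambda z: np.ones_like(z))
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype))
    if name == "elu":
        return (
            lambda z: np.where(z > 0, z, np.expm1(np.minimum(z, 0.0))),
            lambda z: np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0))),
        )
    if name == "selu":
        return (
            lambda z: _SELU_LAMBDA
            * np.where(z > 0, z, _SELU_ALPHA * np.expm1(np.minimum(z, 0.0))),
            lambda z: _SELU_LAMBDA
            * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0))),
        )
    raise ValueError(f"unknown activation {name!r}")


class Layer:
    """Base layer: lazily built on first forward pass."""

    trainable = False

    #: attributes that cache forward-pass tensors; dropped on pickling
    _transient = ("_x", "_z", "_dwout", "_mask", "_n")

    def __getstate__(self):
        state = {k: v for k, v in self.__dict__.items() if k not in self._transient}
        state.pop("_act", None)
        state.pop("_dact", None)
        return state

    def __setstate__(self, state):
        self.__dict__.update(state)
        if "activation" in state:
            self._act, self._dact = _activation(self.activation)

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    trainable = True

    def __init__(self, units: int, activation: str = "linear") -> None:
        self.units = units
        self.activation = activation
        self._act, self._dact = _activation(activation)

    def build(self, input_shape, rng):
        (d,) = input_shape
        # He-style init, well-behaved for relu/elu/selu alike.
        self.W = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, self.units))
        self.b = np.zeros(self.units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        return (self.units,)

    def forward(self, x, training):
        self._x = x
        self._z = x @ self.W + self.b
        return self._act(self._z)

    def backward(self, grad):
        dz = grad * self._dact(self._z)
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def build(self, input_shape, rng):
        self._rng = rng
        return input_shape

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, grad):
        return grad.reshape((self._n, *self._shape))


class AveragePooling2D(Layer):
    """Non-overlapping average pooling; trailing remainder rows/cols dropped."""

    def __init__(self, pool: tuple[int, int] = (2, 1)) -> None:
        self.pool = pool

    def build(self, input_shape, rng):
        h, w, c = input_shape
        ph, pw = self.pool
        self._out = (h // ph, w // pw, c)
        if self._out[0] == 0 or self._out[1] == 0:
            raise ValueError(f"pool {self.pool} larger than input {input_shape}")
        return self._out

    def forward(self, x, training):
        ph, pw = self.pool
        ho, wo, c = self._out
        self._in_shape = x.shape
        x = x[:, : ho * ph, : wo * pw, :]
        return x.reshape(x.shape[0], ho, ph, wo, pw, c).mean(axis=(2, 4))

    def backward(self, grad):
        ph, pw = self.pool
        n, ho, wo, c = grad.shape
        g = np.zeros(self._in_shape)
        spread = grad[:, :, None, :, None, :] / (ph * pw)
        g[:, : ho * ph, : wo * pw, :] = np.broadcast_to(
            spread, (n, ho, ph, wo, pw, c)
        ).reshape(n, ho * ph, wo * pw, c)
        return g


class SeparableConv2D(Layer):
    """Depthwise-separable convolution: per-channel spatial filter, then 1x1 mix.

    Valid padding, stride 1, channels-last.
    """

    trainable = True

    def __init__(self, filters: int, kernel: tuple[int, int], activation: str = "selu"):
        self.filters = filters
        self.kernel = kernel
        self.activation = activation
        self._act, self._dact = _activation(activation)

    def build(self, input_shape, rng):
        h, w, c = input_shape
        kh, kw = self.kernel
        if kh > h or kw > w:
            raise ValueError(f"kernel {self.kernel} larger than input {input_shape}")
        self.Kd = rng.normal(0.0, np.sqrt(2.0 / (kh * kw)), size=(kh, kw, c))
        self.Wp = rng.normal(0.0, np.sqrt(2.0 / c), size=(c, self.filters))
        self.b = np.zeros(self.filters)
        self.dKd = np.zeros_like(self.Kd)
        self.dWp = np.zeros_like(self.Wp)
        self.db = np.zeros_like(self.b)
        self._out_hw = (h - kh + 1, w - kw + 1)
        return (*self._out_hw, self.filters)

    def forward(self, x, training):
        kh, kw = self.kernel
        ho, wo = self._out_hw
        self._x = x
        dw = np.zeros((x.shape[0], ho, wo, x.shape[3]))
        for a in range(kh):
            for b_ in range(kw):
                dw += x[:, a : a + ho, b_ : b_ + wo, :] * self.Kd[a, b_, :]
        self._dwout = dw
        self._z = dw @ self.Wp + self.b
        return self._act(self._z)

    def backward(self, grad):
        kh, kw = self.kernel
        ho, wo = self._out_hw
        dz = grad * self._dact(self._z)
        self.dWp[...] = np.tensordot(self._dwout, dz, axes=([0, 1, 2], [0, 1, 2]))
        self.db[...] = dz.sum(axis=(0, 1, 2))
        d_dw = dz @ self.Wp.T
        dx = np.zeros_like(self._x)
        for a in range(kh):
            for b_ in range(kw):
                patch = self._x[:, a : a + ho, b_ : b_ + wo, :]
                self.dKd[a, b_, :] = np.sum(patch * d_dw, axis=(0, 1, 2))
                dx[:, a : a + ho, b_ : b_ + wo, :] += d_dw * self.Kd[a, b_, :]
        return dx

    def params(self):
        return [self.Kd, self.Wp, self.b]

    def grads(self):
        return [self.dKd, self.dWp, self.db]


@dataclass
class History:
    """Per-epoch training/validation loss (MSE)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


class NaNLossError(RuntimeError):
    """Training loss became non-finite."""


class Network:
    """A small sequential network trained by Adam on MSE loss."""

    def __init__(self, layers: Sequence[Layer], input_shape: tuple, seed: int = 0):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        if shape != (1,):
            raise ValueError(f"network must emit one scalar per example, got {shape}")
        self._rng = rng
        self._adam_m = [np.zeros_like(p) for layer in self.layers for p in layer.params()]
        self._adam_v = [np.zeros_like(p) for layer in self.layers for p in layer.params()]
        self._adam_t = 0

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float), training=False)[:, 0]

    # -- training ----------------------------------------------------------
    def _all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def _all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self._all_params(), self._all_grads(),
                              self._adam_m, self._adam_v):
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def weights_checksum(self) -> float:
        """Deterministic scalar fingerprint of all weights."""
        return float(sum(np.sum(np.abs(p)) for p in self._all_params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self._all_params(), weights):
            p[...] = w

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 32,
        lr: float = 1e-3,
        validation_split: float = 0.2,
        patience: int = 10,
    ) -> History:
        """Mini-batch Adam on MSE with validation split and early stopping.

        The trailing ``validation_split`` fraction of a seeded shuffle is
        held out; training stops when validation loss has not improved for
        ``patience`` epochs and the best weights are restored.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        n = len(x)
        rng = np.random.default_rng(self.seed + 1)
        perm = rng.permutation(n)
        n_val = int(round(n * validation_split))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr = x[train_idx], y[train_idx]
        x_val, y_val = x[val_idx], y[val_idx]

        history = History()
        best_val = np.inf
        best_weights = self.get_weights()
        wait = 0
        for epoch in range(epochs):
            order = rng.permutation(len(x_tr))
            epoch_loss = 0.0
            for start in range(0, len(x_tr), batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x_tr[idx], y_tr[idx]
                pred = self.forward(xb, training=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise NaNLossError(
                        f"non-finite training loss at epoch {epoch + 1}; "
                        "reduce the learning rate or check the inputs"
                    )
                epoch_loss += loss * len(xb)
                for layer in reversed(self.layers):
                    err = layer.backward(err)
                # MSE gradient scale: 2/batch applied once, post-backprop,
                # via lr folding is avoided — grads already hold d(sum e^2)/2;
                # normalise here.
                for g in self._all_grads():
                    g *= 2.0 / len(xb)
                self._adam_step(lr)
            history.train_loss.append(epoch_loss / len(x_tr))
            if n_val:
                val_pred = self.forward(x_val, training=False)
                val_loss = float(np.mean((val_pred - y_val) ** 2))
            else:
                val_loss = history.train_loss[-1]
            history.val_loss.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = self.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        history.stopped_epoch = len(history.train_loss)
        self.set_weights(best_weights)
        return history
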