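"""Minimal feed-forward neural-network engine on numpy.

Implements exactly what the genotype-to-phenotype regressors and the VAE
need: dense and 1-D convolution layers with He-normal initialization and
L1/L2 kernel penalties, leaky-ReLU activations, max/average pooling,
flattening, the Adam optimizer, and a mini-batch training loop with early
stopping that restores the best-validation weights.  All randomness flows
through an explicit numpy Generator, so training is bit-reproducible for a
fixed seed in a fixed environment.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def forward(self, x):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []

    def penalty(self):
        return 0.0


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, l1=0.0, l2=0.0):
        # He-normal: std = sqrt(2 / fan_in)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.l1, self.l2 = l1, l2

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self._gW = self._x.T @ grad + self.l1 * np.sign(self.W) + 2.0 * self.l2 * self.W
        self._gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self._gW, self._gb]

    def penalty(self):
        return self.l1 * np.abs(self.W).sum() + self.l2 * np.square(self.W).sum()


class LeakyReLU(Layer):
    def __init__(self, alpha=0.3):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Conv1D(Layer):
    """Valid-padding 1-D convolution over the marker axis, single input channel.

    Input (batch, length); output (batch, length - kernel + 1, filters).
    """

    def __init__(self, kernel_size, filters, rng, l1=0.0, l2=0.0):
        self.kernel_size, self.filters = kernel_size, filters
        self.W = rng.normal(0.0, np.sqrt(2.0 / kernel_size), size=(kernel_size, filters))
        self.b = np.zeros(filters)
        self.l1, self.l2 = l1, l2

    def forward(self, x):
        if x.shape[1] < self.kernel_size:
            raise ValueError("input shorter than convolution kernel")
        self._win = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=1)
        return np.tensordot(self._win, self.W, axes=([2], [0])) + self.b

    def backward(self, grad):
        self._gW = (
            np.tensordot(self._win, grad, axes=([0, 1], [0, 1]))
            + self.l1 * np.sign(self.W)
            + 2.0 * self.l2 * self.W
        )
        self._gb = grad.sum(axis=(0, 1))
        batch, out_len, _ = grad.shape
        gx = np.zeros((batch, out_len + self.kernel_size - 1))
        gW_free = grad @ self.W.T  # (batch, out_len, kernel)
        for k in range(self.kernel_size):
            gx[:, k : k + out_len] += gW_free[:, :, k]
        return gx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self._gW, self._gb]

    def penalty(self):
        return self.l1 * np.abs(self.W).sum() + self.l2 * np.square(self.W).sum()


class Pool1D(Layer):
    """Non-overlapping max or average pooling along axis 1; trailing remainder dropped."""

    def __init__(self, pool_size, mode="max"):
        if mode not in ("max", "average"):
            raise ValueError("pool mode must be 'max' or 'average'")
        self.pool_size, self.mode = pool_size, mode

    def forward(self, x):
        b, L, f = x.shape
        nw = L // self.pool_size
        if nw == 0:
            raise ValueError("input shorter than pooling window")
        self._in_shape = x.shape
        xw = x[:, : nw * self.pool_size].reshape(b, nw, self.pool_size, f)
        if self.mode == "max":
            self._arg = xw.argmax(axis=2)
            return xw.max(axis=2)
        self._nw = nw
        return xw.mean(axis=2)

    def backward(self, grad):
        b, L, f = self._in_shape
        nw = L // self.pool_size
        gx = np.zeros((b, nw, self.pool_size, f))
        if self.mode == "max":
            bi, wi, fi = np.ogrid[:b, :nw, :f]
            gx[bi, wi, self._arg, fi] = grad
        else:
            gx += (grad / self.pool_size)[:, :, None, :]
        out = np.zeros(self._in_shape)
        out[:, : nw * self.pool_size] = gx.reshape(b, nw * self.pool_size, f)
        return out


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def penalty(self):
        return sum(layer.penalty() for layer in self.layers)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def predict(self, X):
        out = self.forward(np.asarray(X, dtype=float))
        return out.reshape(len(out), -1)[:, 0] if out.ndim > 1 and out.shape[-1] == 1 else out


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def iterate_minibatches(n, batch_size, rng, shuffle=True):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_regressor(
    net: Sequential,
    X_train,
    y_train,
    X_val,
    y_val,
    *,
    learning_rate,
    batch_size,
    max_epochs,
    patience,
    rng,
) -> dict:
    """Mini-batch MSE training with early stopping on validation loss.

    Returns a history dict with per-epoch train/validation MSE; the network
    is left holding the weights of the best-validation epoch.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).reshape(-1, 1)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).reshape(-1, 1)

    opt = Adam(net.params(), lr=learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_weights, since_best = np.inf, net.get_weights(), 0
    for epoch in range(max_epochs):
        train_se = 0.0
        for idx in iterate_minibatches(len(X_train), batch_size, rng):
            xb, yb = X_train[idx], y_train[idx]
            pred = net.forward(xb)
            err = pred - yb
            train_se += float(np.sum(err**2))
            net.backward(2.0 * err / len(xb))
            opt.step(net.grads())
        val_pred = net.forward(X_val)
        if not np.all(np.isfinite(val_pred)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; lower the learning rate or penalties"
            )
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history["train_loss"].append(train_se / len(X_train))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val, best_weights, since_best = val_loss, net.get_weights(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_weights(best_weights)
    history["best_val_loss"] = best_val if np.isfinite(best_val) else None
    return history
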