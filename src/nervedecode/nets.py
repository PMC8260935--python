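"""Minimal NumPy neural-network framework for the shallow decoders.

Implements exactly the building blocks the decoder architectures need
(1-D convolution over time, dense, LSTM, dropout), the Adam optimizer with
the decoding paradigm's hyperparameters (beta1=0.99, beta2=0.999, L2=1e-5),
and a plateau learning-rate scheduler (drop by 10x after 2 non-improving
epochs). Gradients are verified against central differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts in place."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Conv1d(Layer):
    """Valid cross-correlation over the last (time) axis of (B, C, T)."""

    def __init__(self, n_in: int, n_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        fan_in = n_in * kernel
        self.params["w"] = _glorot(rng, (n_out, n_in, kernel), fan_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        cols = sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        self._cols = cols
        self._x_shape = x.shape
        y = np.einsum("bctk,ock->bot", cols, self.params["w"],
                      optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, dout):
        k, s = self.kernel, self.stride
        self.grads["w"] = np.einsum(
            "bctk,bot->ock", self._cols, dout, optimize=True
        )
        self.grads["b"] = dout.sum(axis=(0, 2))
        dx = np.zeros(self._x_shape)
        t_out = dout.shape[2]
        w = self.params["w"]
        for kk in range(k):
            # y[b,o,t] draws from x[b,c,t*s+kk]
            dx[:, :, kk : kk + s * t_out : s][:, :, :t_out] += np.einsum(
                "bot,oc->bct", dout, w[:, :, kk], optimize=True
            )
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; the trainer assigns ``rng`` before training."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng not set before training")
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Transpose(Layer):
    """(B, C, T) <-> (B, T, C) adapter between conv and recurrent stacks."""

    def forward(self, x, train=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dout):
        return np.ascontiguousarray(dout.transpose(0, 2, 1))


class LSTM(Layer):
    """Single LSTM layer over (B, T, I); returns the full hidden sequence
    or only the final hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        super().__init__()
        self.h = n_hidden
        self.return_sequences = return_sequences
        self.params["wx"] = _glorot(rng, (n_in, 4 * n_hidden), n_in, n_hidden)
        self.params["wh"] = _glorot(
            rng, (n_hidden, 4 * n_hidden), n_hidden, n_hidden
        )
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.params["b"] = b

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x, train=False):
        b_sz, t_len, _ = x.shape
        h = self.h
        wx, wh, bias = self.params["wx"], self.params["wh"], self.params["b"]
        h_t = np.zeros((b_sz, h))
        c_t = np.zeros((b_sz, h))
        self._x = x
        self._cache = []
        hs = np.empty((b_sz, t_len, h))
        for t in range(t_len):
            z = x[:, t] @ wx + h_t @ wh + bias
            i = self._sigmoid(z[:, :h])
            f = self._sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = self._sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h_t, c_t, i, f, g, o, tanh_c))
            h_t, c_t = h_new, c_new
            hs[:, t] = h_t
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x = self._x
        b_sz, t_len, _ = x.shape
        h = self.h
        wx, wh = self.params["wx"], self.params["wh"]
        d_wx = np.zeros_like(wx)
        d_wh = np.zeros_like(wh)
        d_b = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_sz, h))
        dc_next = np.zeros((b_sz, h))
        for t in range(t_len - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t] + dh_next
            else:
                dh = (dout if t == t_len - 1 else 0.0) + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            d_wx += x[:, t].T @ dz
            d_wh += h_prev.T @ dz
            d_b += dz.sum(axis=0)
            dx[:, t] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * f
        self.grads["wx"] = d_wx
        self.grads["wh"] = d_wh
        self.grads["b"] = d_b
        return dx


class TimeDense(Layer):
    """Per-time-step linear output projection on (B, T, H)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["w"] = x2.T @ d2
        self.grads["b"] = d2.sum(axis=0)
        return dout @ self.params["w"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]

    def param_count(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def layer_counts(self) -> tuple[int, int, int]:
        """(conv, lstm, fully-connected) layer counts; the per-time-step
        output projection (TimeDense) counts as the recurrent stack's head,
        not a fully-connected layer."""
        conv = sum(isinstance(l, Conv1d) for l in self.layers)
        lstm = sum(isinstance(l, LSTM) for l in self.layers)
        fc = sum(isinstance(l, Dense) for l in self.layers)
        return conv, lstm, fc


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, model: Sequential, lr: float = 0.005,
                 beta1: float = 0.99, beta2: float = 0.999,
                 weight_decay: float = 1e-5, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {id(l) * 1000 + i: np.zeros_like(l.params[k])
                   for i, (l, k) in enumerate(model.parameters())}
        self._v = {key: np.zeros_like(v) for key, v in self._m.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, key) in enumerate(self.model.parameters()):
            slot = id(layer) * 1000 + i
            g = layer.grads[key] + self.weight_decay * layer.params[key]
            m = self._m[slot] = b1 * self._m[slot] + (1 - b1) * g
            v = self._v[slot] = b2 * self._v[slot] + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            layer.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class PlateauScheduler:
    """Drop the learning rate by ``factor`` whenever the epoch loss has not
    improved for ``patience`` consecutive epochs."""

    def __init__(self, lr_init: float, factor: float = 10.0,
                 patience: int = 2, tol: float = 0.0):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.tol = tol
        self._best = np.inf
        self._bad = 0

    def step(self, loss: float) -> float:
        if loss < self._best - self.tol:
            self._best = loss
            self._bad = 0
        else:
            self._bad += 1
            if self._bad >= self.patience:
                self.lr /= self.factor
                self._bad = 0
        return self.lr


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean element-wise binary cross-entropy on logits; returns (loss,
    dloss/dlogits)."""
    z = logits
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))
    return float(loss), (sig - y) / z.size


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def train_network(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    *,
    loss: str = "mse",
    lr_init: float = 0.005,
    beta1: float = 0.99,
    beta2: float = 0.999,
    weight_decay: float = 1e-5,
    minibatch: int = 38,
    minibatches_per_epoch: int = 10,
    lr_drop_factor: float = 10.0,
    plateau_epochs: int = 2,
    max_epochs: int = 200,
    min_lr: float = 1e-6,
    seed: int = 0,
    sample_prob: np.ndarray | None = None,
) -> list[dict]:
    """Seeded minibatch training loop; returns the per-epoch history
    (epoch loss and learning rate). Training stops at ``max_epochs`` or when
    the plateau scheduler pushes the learning rate below ``min_lr``.

    ``sample_prob`` optionally biases minibatch sampling (used for
    inverse-class-frequency balancing); minibatches are drawn with
    replacement.
    """
    rng = np.random.default_rng(seed)
    model.set_dropout_rng(rng)
    loss_fn = {"mse": mse_loss, "bce": bce_with_logits}[loss]
    optimizer = Adam(model, lr=lr_init, beta1=beta1, beta2=beta2,
                     weight_decay=weight_decay)
    scheduler = PlateauScheduler(lr_init, factor=lr_drop_factor,
                                 patience=plateau_epochs)
    n = x.shape[0]
    history: list[dict] = []
    for epoch in range(max_epochs):
        batch_losses = []
        for _ in range(minibatches_per_epoch):
            idx = rng.choice(n, size=minibatch, replace=True, p=sample_prob)
            pred = model.forward(x[idx], train=True)
            batch_loss, dout = loss_fn(pred, y[idx])
            model.backward(dout)
            optimizer.step()
            batch_losses.append(batch_loss)
        epoch_loss = float(np.mean(batch_losses))
        lr = scheduler.step(epoch_loss)
        optimizer.lr = lr
        history.append({"epoch": epoch, "loss": epoch_loss, "lr": lr})
        if lr < min_lr:
            break
    return history
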