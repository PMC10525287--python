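"""Minimal numpy neural-network engine.

Implements exactly the layer set the sleep-staging architecture needs -
1-D convolution, max pooling, dense layers, tanh, softmax cross-entropy
and (bidirectional) GRU cells - with reverse-mode gradients written out
by hand and Adam / RMSprop / SGD update rules.  Shapes follow the
"channels-last" convention: convolutional tensors are ``(batch, time,
features)``, recurrent inputs ``(batch, steps, features)``.

The engine is deliberately small: full-batch or mini-batch gradient
descent on CPU, no autograd, no graph.  Gradient correctness is enforced
by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Tanh",
    "GRU",
    "BiGRU",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "make_optimizer",
    "get_initializer",
]


# ---------------------------------------------------------------------------
# initializers

def _glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _he_normal(rng, shape, fan_in, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _random_normal(rng, shape, fan_in, fan_out):
    return rng.normal(0.0, 0.05, size=shape)


def _orthogonal(rng, shape, fan_in, fan_out):
    a = rng.normal(size=shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


def _zeros(rng, shape, fan_in, fan_out):
    return np.zeros(shape)


_INITIALIZERS = {
    "glorot_uniform": _glorot_uniform,
    "he_normal": _he_normal,
    "random_normal": _random_normal,
    "orthogonal": _orthogonal,
    "zeros": _zeros,
}


def get_initializer(name: str):
    try:
        return _INITIALIZERS[name]
    except KeyError:
        raise ValueError(
            f"unknown initializer {name!r}; choose from {sorted(_INITIALIZERS)}"
        ) from None


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, kernel_init="glorot_uniform", bias_init="zeros"):
        super().__init__()
        w_init = get_initializer(kernel_init)
        b_init = get_initializer(bias_init)
        self.params = {
            "W": w_init(rng, (n_in, n_out), n_in, n_out),
            "b": b_init(rng, (n_out,), n_in, n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class Conv1D(Layer):
    """Valid-mode 1-D convolution (cross-correlation), stride 1.

    Input ``(N, L)`` or ``(N, L, 1)``; output ``(N, L-K+1, F)``.
    As the front layer of every network here, it does not propagate a
    gradient to its input.
    """

    def __init__(self, n_filters, kernel_size, rng, kernel_init="glorot_uniform", bias_init="zeros"):
        super().__init__()
        w_init = get_initializer(kernel_init)
        b_init = get_initializer(bias_init)
        self.kernel_size = int(kernel_size)
        self.n_filters = int(n_filters)
        self.params = {
            "W": w_init(rng, (n_filters, kernel_size), kernel_size, n_filters),
            "b": b_init(rng, (n_filters,), kernel_size, n_filters),
        }

    def forward(self, x):
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[..., 0]
        if x.shape[1] < self.kernel_size:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel_size}"
            )
        self._windows = np.lib.stride_tricks.sliding_window_view(
            x, self.kernel_size, axis=1
        )  # (N, T, K)
        return self._windows @ self.params["W"].T + self.params["b"]

    def backward(self, gout):
        # gout: (N, T, F)
        self.grads["W"] = np.einsum("ntk,ntf->fk", self._windows, gout)
        self.grads["b"] = gout.sum(axis=(0, 1))
        return None


class MaxPool1D(Layer):
    def __init__(self, pool_size=2, stride=2):
        super().__init__()
        self.pool_size = int(pool_size)
        self.stride = int(stride)

    def forward(self, x):
        n, t, f = x.shape
        t_out = (t - self.pool_size) // self.stride + 1
        idx = np.arange(t_out)[:, None] * self.stride + np.arange(self.pool_size)
        windows = x[:, idx, :]  # (N, T_out, pool, F)
        self._arg = windows.argmax(axis=2)
        self._in_shape = x.shape
        self._idx = idx
        return windows.max(axis=2)

    def backward(self, gout):
        n, t_out, f = gout.shape
        gin = np.zeros(self._in_shape)
        ni, ti, fi = np.meshgrid(
            np.arange(n), np.arange(t_out), np.arange(f), indexing="ij"
        )
        src = self._idx[ti, self._arg]
        np.add.at(gin, (ni, src, fi), gout)
        return gin


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y**2)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRU(Layer):
    """Single-direction GRU (classic gate-before-candidate formulation).

    Input ``(N, T, D)``.  ``return_sequences`` yields ``(N, T, U)``,
    otherwise the final hidden state ``(N, U)``.

    Gates::

        z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
        r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
        c_t = tanh(x_t Wc + (r_t * h_{t-1}) Uc + bc)
        h_t = (1 - z_t) * h_{t-1} + z_t * c_t
    """

    def __init__(self, n_in, units, rng, return_sequences=False, reverse=False,
                 kernel_init="glorot_uniform", bias_init="zeros"):
        super().__init__()
        self.units = int(units)
        self.return_sequences = return_sequences
        self.reverse = reverse
        w_init = get_initializer(kernel_init)
        b_init = get_initializer(bias_init)
        self.params = {}
        for g in ("z", "r", "c"):
            self.params[f"W{g}"] = w_init(rng, (n_in, units), n_in, units)
            self.params[f"U{g}"] = _orthogonal(rng, (units, units), units, units)
            self.params[f"b{g}"] = b_init(rng, (units,), n_in, units)

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1, :]
        n, t, d = x.shape
        p = self.params
        h = np.zeros((n, self.units))
        self._x = x
        self._cache = []
        hs = np.empty((n, t, self.units))
        for step in range(t):
            xt = x[:, step, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            rh = r * h
            c = np.tanh(xt @ p["Wc"] + rh @ p["Uc"] + p["bc"])
            h_new = (1.0 - z) * h + z * c
            self._cache.append((xt, h, z, r, rh, c))
            h = h_new
            hs[:, step, :] = h
        self._hs = hs
        if self.return_sequences:
            return hs[:, ::-1, :] if self.reverse else hs
        return h

    def backward(self, gout):
        p = self.params
        n, t, d = self._x.shape
        self.zero_grads()
        g = self.grads
        gx = np.zeros_like(self._x)
        if self.return_sequences:
            gh_seq = gout[:, ::-1, :] if self.reverse else gout
            gh_next = np.zeros((n, self.units))
        else:
            gh_seq = None
            gh_next = gout
        for step in range(t - 1, -1, -1):
            gh = gh_next.copy()
            if gh_seq is not None:
                gh += gh_seq[:, step, :]
            xt, h_prev, z, r, rh, c = self._cache[step]
            gz = gh * (c - h_prev) * z * (1.0 - z)
            gc = gh * z * (1.0 - c**2)
            grh = gc @ p["Uc"].T
            gr = grh * h_prev * r * (1.0 - r)
            gh_prev = gh * (1.0 - z) + grh * r
            gh_prev += gz @ p["Uz"].T + gr @ p["Ur"].T
            g["Wz"] += xt.T @ gz
            g["Wr"] += xt.T @ gr
            g["Wc"] += xt.T @ gc
            g["Uz"] += h_prev.T @ gz
            g["Ur"] += h_prev.T @ gr
            g["Uc"] += rh.T @ gc
            g["bz"] += gz.sum(axis=0)
            g["br"] += gr.sum(axis=0)
            g["bc"] += gc.sum(axis=0)
            gxt = gz @ p["Wz"].T + gr @ p["Wr"].T + gc @ p["Wc"].T
            gx[:, step, :] = gxt
            gh_next = gh_prev
        if self.reverse:
            gx = gx[:, ::-1, :]
        return gx


class BiGRU(Layer):
    """Bidirectional GRU: forward + time-reversed GRU, outputs concatenated."""

    def __init__(self, n_in, units, rng, return_sequences=False,
                 kernel_init="glorot_uniform", bias_init="zeros"):
        super().__init__()
        self.fwd = GRU(n_in, units, rng, return_sequences=return_sequences,
                       reverse=False, kernel_init=kernel_init, bias_init=bias_init)
        self.bwd = GRU(n_in, units, rng, return_sequences=return_sequences,
                       reverse=True, kernel_init=kernel_init, bias_init=bias_init)
        self.units = int(units)
        self.return_sequences = return_sequences

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x):
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, gout):
        gf = gout[..., : self.units]
        gb = gout[..., self.units :]
        return self.fwd.backward(gf) + self.bwd.backward(gb)

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()


# ---------------------------------------------------------------------------
# loss

def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, y_onehot):
    """Mean cross-entropy; returns ``(loss, probs, grad_wrt_logits)``."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.sum(y_onehot * np.log(p + eps)) / n
    grad = (p - y_onehot) / n
    return loss, p, grad


# ---------------------------------------------------------------------------
# container + optimizers

class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout):
        g = gout
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break
        return g

    def param_layers(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, BiGRU):
                out.extend(layer.sublayers)
            elif layer.params:
                out.append(layer)
        return out

    def get_weights(self):
        return [
            {k: v.copy() for k, v in layer.params.items()}
            for layer in self.param_layers()
        ]

    def set_weights(self, weights):
        for layer, saved in zip(self.param_layers(), weights, strict=True):
            for k in layer.params:
                layer.params[k] = saved[k].copy()


class _Optimizer:
    def __init__(self, lr):
        self.lr = lr
        self.state: dict[tuple[int, str], dict] = {}

    def update(self, layers):
        for layer in layers:
            for key, param in layer.params.items():
                grad = layer.grads.get(key)
                if grad is None:
                    continue
                self._apply(self.state.setdefault((id(layer), key), {}), param, grad)

    def _apply(self, state, param, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr=0.01, momentum=0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _apply(self, state, param, grad):
        v = state.get("v")
        if v is None:
            v = np.zeros_like(param)
        v = self.momentum * v - self.lr * grad
        state["v"] = v
        param += v


class Adam(_Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _apply(self, state, param, grad):
        m = state.get("m", np.zeros_like(param))
        v = state.get("v", np.zeros_like(param))
        t = state.get("t", 0) + 1
        m = self.beta1 * m + (1 - self.beta1) * grad
        v = self.beta2 * v + (1 - self.beta2) * grad**2
        state.update(m=m, v=v, t=t)
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _apply(self, state, param, grad):
        v = state.get("v", np.zeros_like(param))
        v = self.rho * v + (1 - self.rho) * grad**2
        state["v"] = v
        param -= self.lr * grad / (np.sqrt(v) + self.eps)


_OPTIMIZERS = {"adam": Adam, "sgd": SGD, "rmsprop": RMSprop}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(lr=lr)
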