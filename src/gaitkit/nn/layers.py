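"""Layer primitives with explicit forward/backward passes.

All layers operate on float32 arrays in NHWC layout (batch, height, width,
channels) or (batch, features) for dense layers.  Each layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the cache and
stores parameter gradients on the layer (``.grads``) while returning the
gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: a differentiable transform with optional parameters."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def state(self) -> dict:
        """Non-trainable state (e.g. batch-norm moving statistics)."""
        return {}

    def n_parameters(self) -> int:
        total = sum(int(np.prod(p.shape)) for p in self.params().values())
        total += sum(int(np.prod(s.shape)) for s in self.state().values())
        return total

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution with stride 2 and TensorFlow-style 'same' padding.

    With an even input size H the output has size H/2 and the required total
    padding is 1 pixel per axis, applied on the bottom/right (the convention
    of 'same' padding with stride 2).  Weights are stored as
    (kh, kw, c_in, c_out) and initialized Glorot-uniform.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=2, rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride = kernel, stride
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit,
                             size=(kernel, kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None
        # training loops may disable the input gradient of the first layer
        self.compute_dx = True

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def _pad(self, x):
        n, h, w, c = x.shape
        oh = -(-h // self.stride)
        ow = -(-w // self.stride)
        ph = max((oh - 1) * self.stride + self.k - h, 0)
        pw = max((ow - 1) * self.stride + self.k - w, 0)
        pads = ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0))
        return np.pad(x, pads), oh, ow, pads

    def _im2col(self, xp, oh, ow):
        # windows: (n, H', W', c, k, k) -> (n*oh*ow, k*k*c) in (kh, kw, c) order
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        win = win[:, ::self.stride, ::self.stride]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, self.k * self.k * xp.shape[3])
        return np.ascontiguousarray(cols)

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        xp, oh, ow, pads = self._pad(x)
        cols = self._im2col(xp, oh, ow)
        wmat = self.W.reshape(-1, self.c_out)
        out = cols @ wmat + self.b
        out = out.reshape(x.shape[0], oh, ow, self.c_out)
        self._cache = (cols, x.shape, xp.shape, pads, oh, ow)
        return out

    def backward(self, dout):
        cols, xshape, xpshape, pads, oh, ow = self._cache
        n = xshape[0]
        dflat = dout.reshape(-1, self.c_out).astype(np.float32)
        self.dW = (cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        if not self.compute_dx:
            return None
        dcols = (dflat @ self.W.reshape(-1, self.c_out).T)
        dcols = dcols.reshape(n, oh, ow, self.k, self.k, xshape[3])
        dxp = np.zeros(xpshape, dtype=np.float32)
        s = self.stride
        for kh in range(self.k):
            for kw in range(self.k):
                dxp[:, kh:kh + s * oh:s, kw:kw + s * ow:s, :] += dcols[:, :, :, kh, kw, :]
        (_, (pt, pb), (pl, pr), _) = pads
        h, w = xshape[1], xshape[2]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, spatial) axes.

    Training mode normalizes with batch statistics and updates exponential
    moving averages; inference mode uses the moving averages.  The moving
    mean/variance count toward the model's parameter total, giving 4 values
    per channel (gamma, beta, moving mean, moving variance).  The default
    momentum of 0.9 lets the moving statistics converge within the tens of
    update steps that small training sets provide.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.moving_mean = np.zeros(channels, dtype=np.float32)
        self.moving_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"moving_mean": self.moving_mean, "moving_var": self.moving_var}

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = (self.momentum * self.moving_mean
                                + (1 - self.momentum) * mu).astype(np.float32)
            self.moving_var = (self.momentum * self.moving_var
                               + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes, training, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv, axes, training, xshape = self._cache
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        if not training:
            return dout * self.gamma * inv
        m = np.prod([xshape[a] for a in axes])
        dxhat = dout * self.gamma
        dx = (inv / m) * (m * dxhat
                          - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate=0.5):
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask
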