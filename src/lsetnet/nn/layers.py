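"""Layers with explicit forward/backward passes.

Parameters live in ``self.params`` (trainable) and ``self.buffers``
(non-trainable running statistics); gradients accumulate in ``self.grads``
under the same keys.  Composite layers expose children through
``self.children`` so that ``named_params`` can walk the tree.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base layer: holds params/grads/buffers and an optional child list."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.children: list[tuple[str, "Layer"]] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self, prefix: str = ""):
        """Yield (path, params-dict, key) triples for every trainable array."""
        for key in self.params:
            yield f"{prefix}{key}", self, key
        for name, child in self.children:
            yield from child.named_params(prefix=f"{prefix}{name}.")

    def n_trainable(self) -> int:
        n = sum(p.size for p in self.params.values())
        return n + sum(c.n_trainable() for _, c in self.children)

    def n_non_trainable(self) -> int:
        n = sum(b.size for b in self.buffers.values())
        return n + sum(c.n_non_trainable() for _, c in self.children)

    def zero_grads(self) -> None:
        for key, p in self.params.items():
            self.grads[key] = np.zeros_like(p)
        for _, child in self.children:
            child.zero_grads()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


def _glorot_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' zero padding, with bias.

    Weight layout is (k, k, in_ch, out_ch).  Implemented via im2col +
    one GEMM; the input-gradient is itself a same-padded convolution of
    the output gradient with the spatially flipped, transposed kernel.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = kernel * kernel * in_ch
        self.params["W"] = _he_init(rng, (kernel, kernel, in_ch, out_ch), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        n, h, w = x.shape[:3]
        return cols.reshape(n * h * w, k * k * x.shape[3])

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None):
        k, _, cin, cout = w.shape
        n, h, ww = x.shape[:3]
        cols = Conv2d._im2col(x, k)
        out = cols @ w.reshape(k * k * cin, cout)
        if b is not None:
            out += b
        return out.reshape(n, h, ww, cout), cols

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[-1]}")
        y, cols = self._conv(x, self.params["W"], self.params["b"])
        # keep the unfolded input during training; at eval keep only a
        # reference so attribution backprop can rebuild it on demand
        self._cols = cols if training else None
        self._x = None if training else x
        self._xshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, cin, cout = self.k, self.in_ch, self.out_ch
        if self._cols is None:
            self._cols = self._im2col(self._x, k)
        dy2 = dy.reshape(-1, cout)
        self.grads["b"] = dy2.sum(axis=0)
        self.grads["W"] = (self._cols.T @ dy2).reshape(k, k, cin, cout)
        w_flip = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,out,in)
        dx, _ = self._conv(dy, np.ascontiguousarray(w_flip))
        self._cols = None
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=F32)
        self.params["beta"] = np.zeros(ch, dtype=F32)
        self.buffers["running_mean"] = np.zeros(ch, dtype=F32)
        self.buffers["running_var"] = np.ones(ch, dtype=F32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"] + m * mu).astype(F32)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"] + m * var).astype(F32)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (xhat, invstd.astype(F32), training)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, was_training = self._cache
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not was_training:
            return dy * g * invstd
        m = float(np.prod([dy.shape[a] for a in axes]))
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * invstd
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped
    (floor division of the spatial size, matching the 31->15->7 schedule)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        r = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = r.argmax(axis=-1)
        self._xshape = x.shape
        return r.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dr, self._argmax[..., None], dy[..., None], axis=-1)
        dxc = dr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h2, 2 * w2, c)
        if (h, w) == (2 * h2, 2 * w2):
            return dxc
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = dxc
        return dx


class Dense(Layer):
    """Affine layer applied to the last axis (works for 2-D and 3-D inputs)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, init: str = "glorot"):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        if init == "he":
            self.params["W"] = _he_init(rng, (in_dim, out_dim), in_dim)
        else:
            self.params["W"] = _glorot_init(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim, dtype=F32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x2 = x.reshape(-1, self.in_dim) if training else None
        self._xshape = x.shape
        y = x.reshape(-1, self.in_dim) @ self.params["W"] + self.params["b"]
        return y.reshape(*x.shape[:-1], self.out_dim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.out_dim)
        self.grads["W"] = self._x2.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        dx = dy2 @ self.params["W"].T
        self._x2 = None
        return dx.reshape(self._xshape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LayerNorm(Layer):
    """Layer normalization over the last axis with affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.params["gamma"] = np.ones(dim, dtype=F32)
        self.params["beta"] = np.zeros(dim, dtype=F32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * invstd
        self._invstd = invstd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.grads["gamma"] = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.grads["beta"] = dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.params["gamma"]
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * invstd
        return dx.astype(F32, copy=False)


class SEBlock(Layer):
    """Squeeze-and-excitation channel recalibration.

    Squeeze: global average over the spatial grid per channel.
    Excitation: dense(C -> max(1, C/r), ReLU) then dense(-> C, sigmoid).
    The input is rescaled channel-wise by the sigmoid gates.
    """

    def __init__(self, ch: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.ch = ch
        self.hidden = max(1, ch // reduction)
        self.fc1 = Dense(ch, self.hidden, rng, init="he")
        self.fc2 = Dense(self.hidden, ch, rng)
        self.children = [("fc1", self.fc1), ("fc2", self.fc2)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        s = x.mean(axis=(1, 2))
        a = self.fc1.forward(s, training=True)
        self._relu_mask = a > 0
        a = np.where(self._relu_mask, a, F32(0.0))
        z = self.fc2.forward(a, training=True)
        # overflow-safe sigmoid
        g = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        self._x, self._g = x, g.astype(F32)
        return x * g[:, None, None, :]

    def gates(self) -> np.ndarray:
        """Sigmoid gates of the most recent forward pass, shape (N, C)."""
        return self._g

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, g = self._x, self._g
        n, h, w, c = x.shape
        dg = (dy * x).sum(axis=(1, 2))
        dx = dy * g[:, None, None, :]
        dz = dg * g * (1.0 - g)
        da = self.fc2.backward(dz)
        da = np.where(self._relu_mask, da, F32(0.0))
        ds = self.fc1.backward(da)
        dx += ds[:, None, None, :] / F32(h * w)
        self._x = None
        return dx


class ConvBNReLU(Layer):
    """Conv(3x3, bias) -> BatchNorm -> ReLU, the paper-stack's basic unit."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()
        self.children = [("conv", self.conv), ("bn", self.bn)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class MultiHeadSelfAttention(Layer):
    """Multi-head scaled dot-product self-attention with output projection.

    Q = X W^Q, K = X W^K, V = X W^V (all with bias); per head,
    A = softmax(Q K^T / sqrt(d_k)), Z = A V; heads are concatenated and
    projected by W^O.  d_k = d_model / heads.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % heads != 0:
            raise ValueError("d_model must be divisible by the number of heads")
        self.d, self.h = d_model, heads
        self.dk = d_model // heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)
        self.children = [("wq", self.wq), ("wk", self.wk), ("wv", self.wv), ("wo", self.wo)]

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dk)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        q = self._split(self.wq.forward(x, training=True))
        k = self._split(self.wk.forward(x, training=True))
        v = self._split(self.wv.forward(x, training=True))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(F32(self.dk))
        a = softmax(scores, axis=-1)
        z = a @ v
        self._cache = (q, k, v, a)
        return self.wo.forward(self._merge(z), training=True)

    def attention(self) -> np.ndarray:
        """Attention weights of the last forward pass, (N, heads, T, T)."""
        return self._cache[3]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, a = self._cache
        dz = self._split(self.wo.backward(dy))
        da = dz @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dz
        # softmax Jacobian per row
        dscores = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(F32(self.dk))
        dq = dscores @ k
        dk_ = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk_))
        dx += self.wv.backward(self._merge(dv))
        self._cache = None
        return dx


class FeedForward(Layer):
    """Position-wise FFN: dense(d -> d_ff, ReLU) -> dense(d_ff -> d)."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Dense(d_model, d_ff, rng, init="he")
        self.relu = ReLU()
        self.fc2 = Dense(d_ff, d_model, rng)
        self.children = [("fc1", self.fc1), ("fc2", self.fc2)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.fc2.forward(self.relu.forward(self.fc1.forward(x, training=True)), training=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.fc2.backward(dy)))


class TransformerBlock(Layer):
    """Post-norm transformer encoder block:

        X''  = LayerNorm(X' + MHSA(X'))
        X''' = LayerNorm(X'' + FFN(X''))
    """

    def __init__(self, d_model: int, heads: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.mhsa = MultiHeadSelfAttention(d_model, heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.ln2 = LayerNorm(d_model)
        self.children = [
            ("mhsa", self.mhsa),
            ("ln1", self.ln1),
            ("ffn", self.ffn),
            ("ln2", self.ln2),
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y1 = self.ln1.forward(x + self.mhsa.forward(x, training), training)
        return self.ln2.forward(y1 + self.ffn.forward(y1, training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d1 = self.ln2.backward(dy)
        d1 = d1 + self.ffn.backward(d1)
        d0 = self.ln1.backward(d1)
        return d0 + self.mhsa.backward(d0)
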