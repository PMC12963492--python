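"""Neural-net kernel: gradient checks against finite differences and a
brute-force attention oracle."""

import numpy as np
import pytest

from lsetnet.nn.layers import (
    BatchNorm2d,
    Conv2d,
    Dense,
    LayerNorm,
    MaxPool2d,
    MultiHeadSelfAttention,
    SEBlock,
    TransformerBlock,
    softmax,
)

RNG = np.random.default_rng(1234)


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        hi = f()
        x[i] = old - eps
        lo = f()
        x[i] = old
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def _check_input_grad(layer, x, training=True, tol=2e-2):
    """Backward pass vs central differences of sum(y * w) for random w."""
    y = layer.forward(x.copy(), training=training)
    w = np.random.default_rng(0).standard_normal(y.shape).astype(np.float32)
    layer.forward(x.copy(), training=training)
    dx = layer.backward(w)

    def loss():
        return float((layer.forward(x.copy(), training=training) * w).sum())

    num = _numeric_grad(loss, x)
    denom = np.abs(num).max() + 1e-8
    assert np.abs(dx - num).max() / denom < tol


def test_conv_forward_matches_direct_convolution():
    conv = Conv2d(2, 3, 3, RNG)
    x = RNG.standard_normal((1, 5, 5, 2)).astype(np.float32)
    y = conv.forward(x)
    # direct triple loop with zero padding
    w, b = conv.params["W"], conv.params["b"]
    xp = np.pad(x[0], ((1, 1), (1, 1), (0, 0)))
    expect = np.zeros((5, 5, 3))
    for i in range(5):
        for j in range(5):
            patch = xp[i:i + 3, j:j + 3, :]
            for o in range(3):
                expect[i, j, o] = (patch * w[:, :, :, o]).sum() + b[o]
    assert np.allclose(y[0], expect, atol=1e-4)


def test_conv_input_gradient():
    conv = Conv2d(2, 2, 3, RNG)
    x = RNG.standard_normal((2, 4, 4, 2)).astype(np.float32)
    _check_input_grad(conv, x)


def test_conv_weight_gradient():
    conv = Conv2d(1, 2, 3, RNG)
    x = RNG.standard_normal((1, 4, 4, 1)).astype(np.float32)
    w = RNG.standard_normal((1, 4, 4, 2)).astype(np.float32)
    conv.forward(x, training=True)
    conv.backward(w)
    analytic = conv.grads["W"].copy()

    def loss():
        return float((conv.forward(x, training=True) * w).sum())

    num = _numeric_grad(loss, conv.params["W"])
    assert np.abs(analytic - num).max() / (np.abs(num).max() + 1e-8) < 2e-2


def test_batchnorm_normalizes_and_backward():
    bn = BatchNorm2d(3)
    x = RNG.standard_normal((8, 4, 4, 3)).astype(np.float32) * 3 + 1
    y = bn.forward(x, training=True)
    assert np.abs(y.mean(axis=(0, 1, 2))).max() < 1e-4
    assert np.abs(y.std(axis=(0, 1, 2)) - 1).max() < 1e-3
    _check_input_grad(bn, x, training=True)


def test_batchnorm_eval_uses_running_stats():
    bn = BatchNorm2d(2)
    x = RNG.standard_normal((16, 3, 3, 2)).astype(np.float32)
    for _ in range(50):
        bn.forward(x, training=True)
    y_eval = bn.forward(x, training=False)
    y_train = bn.forward(x, training=True)
    assert np.allclose(y_eval, y_train, atol=1e-2)


def test_maxpool_floor_and_backward():
    pool = MaxPool2d()
    x = RNG.standard_normal((2, 5, 5, 3)).astype(np.float32)
    y = pool.forward(x)
    assert y.shape == (2, 2, 2, 3)  # floor(5/2)
    assert np.allclose(y[0, 0, 0, 0], x[0, :2, :2, 0].max())
    _check_input_grad(pool, x)


def test_se_gates_bounded_and_saturated_identity():
    se = SEBlock(8, RNG, reduction=4)
    x = RNG.standard_normal((3, 4, 4, 8)).astype(np.float32)
    y = se.forward(x, training=True)
    g = se.gates()
    assert np.all(g > 0) and np.all(g < 1)
    # saturate the second dense bias: gates -> 1, output -> x
    se.fc2.params["b"][:] = 50.0
    y = se.forward(x, training=True)
    assert np.allclose(y, x, atol=1e-5)


def test_se_backward():
    se = SEBlock(4, RNG, reduction=2)
    x = RNG.standard_normal((2, 3, 3, 4)).astype(np.float32)
    _check_input_grad(se, x)


def test_se_parameter_counts_closed_form():
    # C=64, r=16 -> hidden 4: 64*4+4 + 4*64+64 = 580
    assert SEBlock(64, np.random.default_rng(0), 16).n_trainable() == 580
    # C=128, r=16 -> hidden 8: 128*8+8 + 8*128+128 = 2184
    assert SEBlock(128, np.random.default_rng(0), 16).n_trainable() == 2184


def _mhsa_oracle(x, layer):
    """Naive per-head, per-position attention, independent of the layer's path."""
    n, t, d = x.shape
    h, dk = layer.h, layer.dk
    q = x @ layer.wq.params["W"] + layer.wq.params["b"]
    k = x @ layer.wk.params["W"] + layer.wk.params["b"]
    v = x @ layer.wv.params["W"] + layer.wv.params["b"]
    out = np.zeros((n, t, d))
    for b in range(n):
        heads = []
        for hi in range(h):
            sl = slice(hi * dk, (hi + 1) * dk)
            z = np.zeros((t, dk))
            for i in range(t):
                scores = np.array([q[b, i, sl] @ k[b, j, sl] for j in range(t)]) / np.sqrt(dk)
                e = np.exp(scores - scores.max())
                a = e / e.sum()
                for j in range(t):
                    z[i] += a[j] * v[b, j, sl]
            heads.append(z)
        out[b] = np.concatenate(heads, axis=1)
    return out @ layer.wo.params["W"] + layer.wo.params["b"]


@pytest.mark.parametrize("t,d,h", [(3, 4, 2), (5, 8, 4), (1, 4, 1)])
def test_mhsa_matches_bruteforce_oracle(t, d, h):
    layer = MultiHeadSelfAttention(d, h, np.random.default_rng(t * 100 + d))
    x = np.random.default_rng(9).standard_normal((2, t, d)).astype(np.float32)
    got = layer.forward(x, training=True)
    assert np.allclose(got, _mhsa_oracle(x.astype(np.float64), layer), atol=1e-5)


def test_mhsa_rows_sum_to_one():
    layer = MultiHeadSelfAttention(8, 2, RNG)
    x = RNG.standard_normal((2, 6, 8)).astype(np.float32)
    layer.forward(x, training=True)
    assert np.allclose(layer.attention().sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_single_token_reduces_to_projection():
    layer = MultiHeadSelfAttention(4, 2, RNG)
    x = RNG.standard_normal((1, 1, 4)).astype(np.float32)
    got = layer.forward(x, training=True)
    v = x @ layer.wv.params["W"] + layer.wv.params["b"]
    expect = v @ layer.wo.params["W"] + layer.wo.params["b"]
    assert np.allclose(got, expect, atol=1e-6)


def test_mhsa_backward():
    layer = MultiHeadSelfAttention(4, 2, np.random.default_rng(5))
    x = np.random.default_rng(6).standard_normal((1, 3, 4)).astype(np.float32)
    _check_input_grad(layer, x, tol=3e-2)


def test_transformer_zeroed_sublayers_reduce_to_double_layernorm():
    blk = TransformerBlock(8, 2, 8, RNG)
    for d in (blk.mhsa.wo, blk.ffn.fc2):
        d.params["W"][:] = 0.0
        d.params["b"][:] = 0.0
    x = RNG.standard_normal((2, 5, 8)).astype(np.float32)
    got = blk.forward(x, training=True)
    ln = LayerNorm(8)
    expect = ln.forward(ln.forward(x.astype(np.float64)))
    assert np.allclose(got, expect, atol=1e-5)
    assert got.shape == x.shape


def test_transformer_backward():
    blk = TransformerBlock(4, 2, 4, np.random.default_rng(2))
    x = np.random.default_rng(3).standard_normal((1, 3, 4)).astype(np.float32)
    _check_input_grad(blk, x, tol=3e-2)


def test_dense_and_layernorm_backward():
    d = Dense(5, 3, np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal((4, 5)).astype(np.float32)
    _check_input_grad(d, x)
    ln = LayerNorm(6)
    x2 = np.random.default_rng(2).standard_normal((3, 6)).astype(np.float32)
    _check_input_grad(ln, x2)


def test_softmax_shift_invariance_and_simplex():
    z = RNG.standard_normal((4, 12))
    p = softmax(z)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.allclose(p, softmax(z + 5.0), atol=1e-12)
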