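"""LSeTNet: lightweight SE-CNN + transformer classifier.

The network is a hybrid stack for 12-class leaf-disease images:

    input (S, S, 3)
      -> conv3x3(64) + BN + ReLU                      (stem)
      -> SE recalibration + 2x2 max-pool              (se_pool)
      -> 3 residual SE blocks (64->128->256->512), each ending in a pool
      -> extra conv block (512, SE, pool)  ->  7x7x512
      -> transformer encoder on the 49 tokens (d_model = 512)
      -> global average pool -> dense(1024, ReLU) -> dropout -> dense(12)

With the default 248x248 input the spatial schedule is
248 -> 124 -> 62 -> 31 -> 15 -> 7 (max-pool with floor division).

A residual SE block computes ``Y = MaxPool(phi(X) + SE(F(X)))`` where
``F`` is two conv-BN-ReLU transforms and ``phi`` is identity when the
channel counts match, else a 1x1 convolution + BN.

Every stage's activation is retained by name on the forward pass and the
gradient with respect to each activation is retained on the backward
pass, which is what Grad-CAM and the embedding extractor consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    Dense,
    Dropout,
    Layer,
    MaxPool2d,
    ReLU,
    SEBlock,
    TransformerBlock,
    softmax,
)

F32 = np.float32


# ---------------------------------------------------------------------------
# declarative configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One architecture stage, declaratively."""

    name: str
    kind: str  # conv_bn | se_pool | residual_se | extra_conv | transformer | gap | dense_head
    in_channels: int
    out_channels: int
    kernel: int = 3
    se_reduction: int = 16
    pool: bool = False
    heads: int = 0
    ffn_width: int = 0


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters from which the network and its report are built."""

    image_size: int = 248
    num_classes: int = 12
    stem_width: int = 64
    block_widths: tuple[int, int, int] = (128, 256, 512)
    se_reduction: int = 16
    heads: int = 8
    ffn_width: int | None = None      # defaults to d_model
    head_hidden: int = 1024
    dropout: float = 0.5
    positional_encoding: bool = False

    @property
    def d_model(self) -> int:
        return self.block_widths[-1]

    def stages(self) -> list[StageSpec]:
        w = self.stem_width
        b1, b2, b3 = self.block_widths
        ffn = self.ffn_width or self.d_model
        return [
            StageSpec("stem", "conv_bn", 3, w),
            StageSpec("se_pool", "se_pool", w, w, se_reduction=self.se_reduction, pool=True),
            StageSpec("res1", "residual_se", w, b1, se_reduction=self.se_reduction, pool=True),
            StageSpec("res2", "residual_se", b1, b2, se_reduction=self.se_reduction, pool=True),
            StageSpec("res3", "residual_se", b2, b3, se_reduction=self.se_reduction, pool=True),
            StageSpec("extra_conv", "extra_conv", b3, b3, se_reduction=self.se_reduction, pool=True),
            StageSpec("transformer", "transformer", b3, b3, heads=self.heads, ffn_width=ffn),
            StageSpec("gap", "gap", b3, b3),
            StageSpec("head", "dense_head", b3, self.num_classes),
        ]

    def spatial_schedule(self) -> list[int]:
        """Spatial side length entering each resolution level (5 pools)."""
        sizes = [self.image_size]
        for _ in range(5):
            sizes.append(sizes[-1] // 2)
        return sizes


def tiny_config(image_size: int = 64, stem_width: int = 16, num_classes: int = 12) -> ModelConfig:
    """A width-reduced configuration for CPU-scale smoke experiments."""
    return ModelConfig(
        image_size=image_size,
        num_classes=num_classes,
        stem_width=stem_width,
        block_widths=(2 * stem_width, 4 * stem_width, 8 * stem_width),
        heads=4,
        head_hidden=16 * stem_width,
    )


# ---------------------------------------------------------------------------
# composite stages
# ---------------------------------------------------------------------------

class SEPoolStage(Layer):
    """SE recalibration followed by a 2x2 max-pool."""

    def __init__(self, ch: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.se = SEBlock(ch, rng, reduction)
        self.pool = MaxPool2d()
        self.children = [("se", self.se)]

    def forward(self, x, training=False):
        return self.pool.forward(self.se.forward(x, training), training)

    def backward(self, dy):
        return self.se.backward(self.pool.backward(dy))


class ResidualSEBlock(Layer):
    """MaxPool(phi(X) + SE(F(X))) with F = two conv-BN-ReLU transforms."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.cbr1 = ConvBNReLU(in_ch, out_ch, rng)
        self.cbr2 = ConvBNReLU(out_ch, out_ch, rng)
        self.se = SEBlock(out_ch, rng, reduction)
        if in_ch == out_ch:
            self.short_conv = None
            self.short_bn = None
            self.children = [("cbr1", self.cbr1), ("cbr2", self.cbr2), ("se", self.se)]
        else:
            self.short_conv = Conv2d(in_ch, out_ch, 1, rng)
            self.short_bn = BatchNorm2d(out_ch)
            self.children = [
                ("cbr1", self.cbr1), ("cbr2", self.cbr2), ("se", self.se),
                ("short_conv", self.short_conv), ("short_bn", self.short_bn),
            ]
        self.pool = MaxPool2d()

    def forward(self, x, training=False):
        f = self.se.forward(self.cbr2.forward(self.cbr1.forward(x, training), training), training)
        if self.short_conv is None:
            s = x
        else:
            s = self.short_bn.forward(self.short_conv.forward(x, training), training)
        return self.pool.forward(f + s, training)

    def backward(self, dy):
        ds = self.pool.backward(dy)
        dx = self.cbr1.backward(self.cbr2.backward(self.se.backward(ds)))
        if self.short_conv is None:
            dx = dx + ds
        else:
            dx = dx + self.short_conv.backward(self.short_bn.backward(ds))
        return dx


class ExtraConvBlock(Layer):
    """Conv-BN-ReLU(512) + SE + pool: prepares the 7x7 transformer input."""

    def __init__(self, ch: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.cbr = ConvBNReLU(ch, ch, rng)
        self.se = SEBlock(ch, rng, reduction)
        self.pool = MaxPool2d()
        self.children = [("cbr", self.cbr), ("se", self.se)]

    def forward(self, x, training=False):
        return self.pool.forward(self.se.forward(self.cbr.forward(x, training), training), training)

    def backward(self, dy):
        return self.cbr.backward(self.se.backward(self.pool.backward(dy)))


def tokenize(fmap: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H*W, C), row-major: token k is pixel (k // W, k % W)."""
    n, h, w, c = fmap.shape
    return fmap.reshape(n, h * w, c)


def detokenize(tokens: np.ndarray, h: int, w: int) -> np.ndarray:
    """Inverse of :func:`tokenize`."""
    n, t, c = tokens.shape
    if t != h * w:
        raise ValueError(f"cannot reshape {t} tokens to {h}x{w}")
    return tokens.reshape(n, h, w, c)


class TokenTransformer(Layer):
    """Tokenize -> transformer encoder block -> detokenize.

    Optionally adds a learned positional embedding to the tokens (off by
    default: the published budget contains no such term).
    """

    def __init__(self, d_model: int, heads: int, d_ff: int, n_tokens: int,
                 rng: np.random.Generator, positional: bool = False):
        super().__init__()
        self.block = TransformerBlock(d_model, heads, d_ff, rng)
        self.children = [("block", self.block)]
        if positional:
            self.params["pos"] = (rng.standard_normal((n_tokens, d_model)) * 0.02).astype(F32)
        self.positional = positional

    def forward(self, x, training=False):
        self._hw = x.shape[1:3]
        t = tokenize(x)
        if self.positional:
            t = t + self.params["pos"]
        return detokenize(self.block.forward(t, training), *self._hw)

    def backward(self, dy):
        dt = self.block.backward(tokenize(dy))
        if self.positional:
            self.grads["pos"] = dt.sum(axis=0)
        return detokenize(dt, *self._hw)


class GlobalAvgPool(Layer):
    """Per-channel spatial mean: g_c = (1 / HW) sum_ij F_c(i, j)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / F32(h * w), self._shape).astype(F32)


class DenseHead(Layer):
    """dense(C -> hidden, ReLU) -> dropout -> dense(hidden -> classes); emits logits."""

    def __init__(self, in_dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator, dropout: float = 0.5):
        super().__init__()
        self.fc1 = Dense(in_dim, hidden, rng, init="he")
        self.relu = ReLU()
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))
        self.fc2 = Dense(hidden, n_classes, rng)
        self.children = [("fc1", self.fc1), ("fc2", self.fc2)]

    def forward(self, x, training=False):
        h = self.drop.forward(self.relu.forward(self.fc1.forward(x, training=True)), training)
        return self.fc2.forward(h, training=True)

    def backward(self, dy):
        return self.fc1.backward(self.relu.backward(self.drop.backward(self.fc2.backward(dy))))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class LSeTNet(Layer):
    """The full network with named per-stage activation/gradient capture."""

    def __init__(self, config: ModelConfig, seed: int = 42):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)

        schedule = config.spatial_schedule()
        if schedule[-1] < 1:
            raise ValueError(
                f"image size {config.image_size} collapses below 1 px over 5 pooling stages"
            )
        self.schedule = schedule
        final = schedule[-1]

        w = config.stem_width
        b1, b2, b3 = config.block_widths
        ffn = config.ffn_width or config.d_model
        r = config.se_reduction
        self.stem = ConvBNReLU(3, w, rng)
        self.se_pool = SEPoolStage(w, rng, r)
        self.res1 = ResidualSEBlock(w, b1, rng, r)
        self.res2 = ResidualSEBlock(b1, b2, rng, r)
        self.res3 = ResidualSEBlock(b2, b3, rng, r)
        self.extra_conv = ExtraConvBlock(b3, rng, r)
        self.transformer = TokenTransformer(
            b3, config.heads, ffn, final * final, rng, config.positional_encoding
        )
        self.gap = GlobalAvgPool()
        self.head = DenseHead(b3, config.head_hidden, config.num_classes, rng, config.dropout)

        self.stage_list: list[tuple[str, Layer]] = [
            ("stem", self.stem),
            ("se_pool", self.se_pool),
            ("res1", self.res1),
            ("res2", self.res2),
            ("res3", self.res3),
            ("extra_conv", self.extra_conv),
            ("transformer", self.transformer),
            ("gap", self.gap),
            ("head", self.head),
        ]
        self.children = list(self.stage_list)
        self.activations: dict[str, np.ndarray] = {}
        self.grad_activations: dict[str, np.ndarray] = {}

    # -- passes ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass returning logits; activations retained by stage name."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[None]
        self.activations = {"input": x}
        for name, stage in self.stage_list:
            x = stage.forward(x, training=training)
            self.activations[name] = x
        self.activations["logits"] = x
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backward pass from a logit seed; per-stage gradients retained."""
        dy = np.asarray(dlogits, dtype=F32)
        self.grad_activations = {"logits": dy}
        for name, stage in reversed(self.stage_list):
            self.grad_activations[name] = dy
            dy = stage.backward(dy)
        self.grad_activations["input"] = dy
        return dy

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities (softmax over logits), evaluated in batches."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[None]
        out = [softmax(self.forward(x[i:i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # -- weights ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for path, layer, key in self.named_params():
            state[path] = layer.params[key].copy()
        for name, stage in self.stage_list:
            for bpath, blayer, bkey in _named_buffers(stage, f"{name}."):
                state[f"buffer:{bpath}"] = blayer.buffers[bkey].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for path, layer, key in self.named_params():
            layer.params[key][...] = state[path]
        for name, stage in self.stage_list:
            for bpath, blayer, bkey in _named_buffers(stage, f"{name}."):
                blayer.buffers[bkey][...] = state[f"buffer:{bpath}"]

    def save_weights(self, path) -> None:
        """Checkpoint all parameters and running statistics as .npz."""
        np.savez_compressed(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def _named_buffers(layer: Layer, prefix: str = ""):
    for key in layer.buffers:
        yield f"{prefix}{key}", layer, key
    for name, child in layer.children:
        yield from _named_buffers(child, f"{prefix}{name}.")


def build_lsetnet(config: ModelConfig | None = None, seed: int = 42) -> LSeTNet:
    """Build the network; identical seeds yield identical initial weights."""
    return LSeTNet(config or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

@dataclass
class ParamReport:
    """Per-stage and total parameter counts.

    ``non_trainable`` counts batch-norm running statistics (2 per BN
    channel).  ``pinned`` holds the sub-stage counts that are exact
    functions of the architecture definition: the stem convolution, the
    first SE block, the transformer block and the dense head.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, trainable, non_trainable)
    pinned: dict[str, int] = field(default_factory=dict)

    @property
    def trainable(self) -> int:
        return sum(t for _, t, _ in self.stages)

    @property
    def non_trainable(self) -> int:
        return sum(n for _, _, n in self.stages)

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    @property
    def size_mb(self) -> float:
        """float32 storage of all parameters, in MiB."""
        return 4.0 * self.total / 2**20

    def to_text(self) -> str:
        lines = [f"{'Stage':<14}{'Trainable':>12}{'Non-trainable':>15}"]
        for name, t, n in self.stages:
            lines.append(f"{name:<14}{t:>12,}{n:>15,}")
        lines.append(f"{'Total':<14}{self.trainable:>12,}{self.non_trainable:>15,}")
        lines.append(f"Total parameters: {self.total:,} ({self.size_mb:.2f} MB)")
        return "\n".join(lines)


def count_parameters(model: LSeTNet) -> ParamReport:
    """Exact parameter accounting for a built model."""
    report = ParamReport()
    for name, stage in model.stage_list:
        report.stages.append((name, stage.n_trainable(), stage.n_non_trainable()))
    report.pinned = {
        "stem_conv": sum(p.size for p in model.stem.conv.params.values()),
        "se_block": model.se_pool.se.n_trainable(),
        "transformer": model.transformer.block.n_trainable(),
        "dense_head": model.head.n_trainable(),
        "non_trainable": report.non_trainable,
    }
    return report
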