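"""Image preprocessing: resize, CLAHE-on-L, Gaussian blur, unsharp masking,
and train-only channel standardization.

The enhancement chain maps valid 8-bit RGB to valid 8-bit RGB and runs in
the fixed order resize -> CLAHE -> blur -> unsharp.  Standardization
``x' = (x - mu) / sigma`` is the only step producing unbounded reals; its
``mu``/``sigma`` are fitted from the training split only, and
:func:`fit_channel_stats` refuses records from any other split so the
guard is structural, not a convention.

CLAHE follows the familiar contrast-limited adaptive histogram
equalization semantics: the luminance channel of LAB space is equalized
tile-wise with per-tile histograms (256 bins) clipped at
``clip_limit x (tile_pixels / 256)``, excess redistributed uniformly,
and per-pixel output bilinearly interpolated between the four
surrounding tile mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate1d
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .manifest import ImageRecord, LeakageError, load_image

logger = logging.getLogger("lsetnet")

SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class PreprocConfig:
    clahe_clip: float = 4.0
    clahe_tiles: tuple[int, int] = (12, 12)
    blur_kernel: int = 9
    blur_sigma: float = 2.0
    unsharp_kernel: int = 7
    unsharp_alpha: float = 1.8
    unsharp_sigma: float | None = None  # derived from the kernel when None
    target_size: int = 248

    def __post_init__(self):
        for k in (self.blur_kernel, self.unsharp_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive, got {k}")
        if self.unsharp_alpha <= 0:
            raise ValueError("unsharp alpha must be > 0")

    @property
    def derived_unsharp_sigma(self) -> float:
        """sigma = 0.3 * ((k - 1)/2 - 1) + 0.8, the kernel-size convention."""
        if self.unsharp_sigma is not None:
            return self.unsharp_sigma
        return 0.3 * ((self.unsharp_kernel - 1) / 2 - 1) + 0.8


@dataclass
class ChannelStats:
    """Per-channel mean/std in pixel-intensity units, training split only."""

    mu: np.ndarray    # (3,)
    sigma: np.ndarray  # (3,), floored at SIGMA_FLOOR

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).reshape(3)
        self.sigma = np.maximum(np.asarray(self.sigma, dtype=np.float64).reshape(3), SIGMA_FLOOR)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "channel,mu,sigma\n"
            + "".join(f"{c},{float(m)!r},{float(s)!r}\n"
                      for c, m, s in zip("RGB", self.mu, self.sigma)),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "ChannelStats":
        lines = Path(path).read_text(encoding="utf-8").strip().splitlines()[1:]
        vals = [line.split(",") for line in lines]
        return cls(mu=[float(v[1]) for v in vals], sigma=[float(v[2]) for v in vals])


# ---------------------------------------------------------------------------
# single-step operations
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Plain bilinear resize to size x size (aspect ratio not preserved).

    Pixel centers are aligned (output center (i+0.5)/scale - 0.5 in input
    coordinates, clamped at the edges).  8-bit input returns 8-bit output.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    if min(image.shape[:2]) < 1 or size < 1:
        raise ValueError("zero-size input or target")
    if image.shape[0] == size and image.shape[1] == size:
        return image.copy()
    out = sk_resize(image.astype(np.float64), (size, size), order=1,
                    mode="edge", anti_aliasing=False, preserve_range=True)
    if image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(image.dtype)


def _clahe_gray(channel: np.ndarray, clip: float, tiles: tuple[int, int]) -> np.ndarray:
    """CLAHE on a single uint8 channel; returns uint8."""
    h0, w0 = channel.shape
    ty, tx = tiles
    if h0 < ty or w0 < tx:
        logger.warning("image %dx%d smaller than CLAHE tile grid %dx%d; shrinking tiles",
                       h0, w0, ty, tx)
        ty, tx = min(ty, h0), min(tx, w0)
    # pad (reflect) to a tile-grid multiple so every tile has the same size;
    # unequal tiles would break spatial invariance on uniform inputs
    th = -(-h0 // ty)
    tw = -(-w0 // tx)
    h, w = th * ty, tw * tx
    channel = np.pad(channel, ((0, h - h0), (0, w - w0)), mode="reflect") \
        if (h, w) != (h0, w0) else channel
    row_edges = np.arange(ty + 1) * th
    col_edges = np.arange(tx + 1) * tw

    # per-tile clipped-histogram mappings (256 -> 256)
    mappings = np.empty((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            tile = channel[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            n = tile.size
            limit = max(1.0, clip * n / 256.0)
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / 256.0
            cdf = hist.cumsum()
            mappings[i, j] = cdf / n * 255.0
    # bilinear interpolation between tile-center mappings
    cy = (row_edges[:-1] + row_edges[1:]) / 2.0
    cx = (col_edges[:-1] + col_edges[1:]) / 2.0
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    yi = np.clip(np.searchsorted(cy, ys) - 1, 0, ty - 2) if ty > 1 else np.zeros(h, int)
    xi = np.clip(np.searchsorted(cx, xs) - 1, 0, tx - 2) if tx > 1 else np.zeros(w, int)
    if ty > 1:
        wy = np.clip((ys - cy[yi]) / (cy[yi + 1] - cy[yi]), 0.0, 1.0)
    else:
        wy = np.zeros(h)
    if tx > 1:
        wx = np.clip((xs - cx[xi]) / (cx[xi + 1] - cx[xi]), 0.0, 1.0)
    else:
        wx = np.zeros(w)

    lut_idx = channel.astype(int)
    yi2 = yi[:, None]
    xi2 = xi[None, :]
    yin = np.minimum(yi2 + 1, ty - 1)
    xin = np.minimum(xi2 + 1, tx - 1)
    m00 = mappings[yi2, xi2, lut_idx]
    m01 = mappings[yi2, xin, lut_idx]
    m10 = mappings[yin, xi2, lut_idx]
    m11 = mappings[yin, xin, lut_idx]
    wy2 = wy[:, None]
    wx2 = wx[None, :]
    out = (1 - wy2) * ((1 - wx2) * m00 + wx2 * m01) + wy2 * ((1 - wx2) * m10 + wx2 * m11)
    return np.clip(np.rint(out[:h0, :w0]), 0, 255).astype(np.uint8)


def clahe_l_channel(image: np.ndarray, config: PreprocConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on the L channel of LAB.

    A/B chroma channels are untouched before the back-conversion; output is
    8-bit RGB in range.
    """
    config = config or PreprocConfig()
    image = np.asarray(image, dtype=np.uint8)
    lab = skcolor.rgb2lab(image.astype(np.float64) / 255.0)
    l8 = np.clip(np.rint(lab[..., 0] / 100.0 * 255.0), 0, 255).astype(np.uint8)
    l8 = _clahe_gray(l8, config.clahe_clip, config.clahe_tiles)
    lab[..., 0] = l8.astype(np.float64) / 255.0 * 100.0
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def gaussian_kernel_1d(kernel: int, sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian sampled at integer offsets, length ``kernel``."""
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    r = kernel // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def gaussian_blur(image: np.ndarray, kernel: int = 9, sigma: float = 2.0) -> np.ndarray:
    """Separable Gaussian convolution with reflection border handling."""
    image = np.asarray(image)
    k1 = gaussian_kernel_1d(kernel, sigma)
    out = image.astype(np.float64)
    out = correlate1d(out, k1, axis=0, mode="reflect")
    out = correlate1d(out, k1, axis=1, mode="reflect")
    if image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(image.dtype)


def unsharp_mask(image: np.ndarray, alpha: float = 1.8, kernel: int = 7,
                 sigma: float | None = None) -> np.ndarray:
    """Sharpen by weighted subtraction of a blurred copy:

        out = clip((1 + alpha) * image - alpha * blur_k(image))

    ``sigma`` defaults to the kernel-size convention 0.3*((k-1)/2 - 1) + 0.8.
    """
    image = np.asarray(image)
    if sigma is None:
        sigma = 0.3 * ((kernel - 1) / 2 - 1) + 0.8
    x = image.astype(np.float64)
    k1 = gaussian_kernel_1d(kernel, sigma)
    blurred = correlate1d(correlate1d(x, k1, axis=0, mode="reflect"), k1, axis=1, mode="reflect")
    out = (1.0 + alpha) * x - alpha * blurred
    if image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return np.clip(out, 0, 255).astype(image.dtype)


# ---------------------------------------------------------------------------
# chain, statistics, standardization
# ---------------------------------------------------------------------------

def enhance(image: np.ndarray, config: PreprocConfig | None = None) -> np.ndarray:
    """The 8-bit enhancement chain: resize -> CLAHE -> blur -> unsharp."""
    config = config or PreprocConfig()
    out = resize_image(np.asarray(image, dtype=np.uint8), config.target_size)
    out = clahe_l_channel(out, config)
    out = gaussian_blur(out, config.blur_kernel, config.blur_sigma)
    return unsharp_mask(out, config.unsharp_alpha, config.unsharp_kernel,
                        config.derived_unsharp_sigma)


def fit_channel_stats(train_records, config: PreprocConfig | None = None,
                      loader=load_image, enhanced: bool = True) -> ChannelStats:
    """Per-channel mean/std over all training pixels after the enhancement chain.

    Accepts ImageRecords (must all be split='train'; anything else raises
    LeakageError) or raw arrays.  Deterministic: plain two-moment
    accumulation in float64.
    """
    n = 0
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    count = 0
    for rec in train_records:
        if isinstance(rec, ImageRecord):
            if rec.split != "train":
                raise LeakageError(
                    f"channel statistics must be fitted on training records only; "
                    f"{rec.image_id} has split={rec.split!r}"
                )
            img = loader(rec.path)
        else:
            img = np.asarray(rec)
        if enhanced:
            img = enhance(img, config)
        x = img.reshape(-1, 3).astype(np.float64)
        acc += x.sum(axis=0)
        acc2 += (x ** 2).sum(axis=0)
        n += x.shape[0]
        count += 1
    if count == 0:
        raise ValueError("no training records provided")
    mu = acc / n
    var = np.maximum(acc2 / n - mu ** 2, 0.0)
    return ChannelStats(mu=mu, sigma=np.sqrt(var))


def standardize(image: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Channel-wise (x - mu) / sigma; real-valued output, not clipped."""
    return (np.asarray(image, dtype=np.float64) - stats.mu) / stats.sigma


def preprocess_pipeline(image: np.ndarray, config: PreprocConfig | None = None,
                        stats: ChannelStats | None = None) -> np.ndarray:
    """Full pipeline: resize -> CLAHE -> blur -> unsharp -> (standardize).

    Without ``stats`` the result is 8-bit RGB; with ``stats`` it is the
    real-valued standardized array.  Applying the pipeline twice is not
    idempotent (CLAHE and unsharp re-amplify), which is expected.
    """
    out = enhance(image, config)
    if stats is not None:
        return standardize(out, stats)
    return out
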