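"""Procedural 12-class leaf-disease image generator.

Three species (Kalanchoe, Neem, Tulsi), each with one healthy and three
disorder classes, mirroring the field-collected class list the pipeline
targets.  Every image is a clutter background + leaf silhouette + veins
+ disorder overlay + lighting jitter, drawn with hard-edged masks so
class signatures are unambiguous color populations:

* web blight    — bright gray filaments and dark necrotic blobs
* yellow        — uniform chlorosis with veins kept green
* yellow blight — chlorosis plus brown marginal necrosis
* leaf spot     — circular brown spots with a darker ring
* downy mildew  — angular yellow patches with gray-purple coating
* yellow spot   — dark lesions ringed by a yellow halo

Signatures are deliberately exaggerated relative to real pathology: the
generator exists to make the pipeline testable end-to-end, not to be
photorealistic.  Generation is a pure function of (seed, class, index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import color as skcolor
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .manifest import DatasetManifest, ImageRecord, save_image

CLASS_NAMES = [
    "Kalanchoe_Healthy",
    "Kalanchoe_Web_Blight",
    "Kalanchoe_Yellow",
    "Kalanchoe_Yellow_Blight",
    "Neem_Healthy",
    "Neem_Spot",
    "Neem_Web_Blight",
    "Neem_Yellow",
    "Tulsi_Downy_Mildew",
    "Tulsi_Healthy",
    "Tulsi_Web_Blight",
    "Tulsi_Yellow_Spot",
]


@dataclass(frozen=True)
class LeafClassSpec:
    """Species base look plus disorder overlay for one class."""

    name: str
    species: str
    disorder: str  # none | web | chlorosis | chlorosis_blight | ring_spot | mildew | halo_spot


def class_specs() -> list[LeafClassSpec]:
    overlay = {
        "Healthy": "none",
        "Web_Blight": "web",
        "Yellow": "chlorosis",
        "Yellow_Blight": "chlorosis_blight",
        "Spot": "ring_spot",
        "Downy_Mildew": "mildew",
        "Yellow_Spot": "halo_spot",
    }
    specs = []
    for name in CLASS_NAMES:
        species, _, disorder_key = name.partition("_")
        specs.append(LeafClassSpec(name, species, overlay[disorder_key]))
    return specs


@dataclass(frozen=True)
class GeneratorConfig:
    image_size: int = 96
    n_per_class: int = 20
    seed: int = 42
    clutter: float = 0.5          # background texture amplitude, 0..1
    lighting_jitter: float = 0.08  # multiplicative brightness jitter half-range

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")


# species base look: superellipse half-axes/exponent, leaf HSV, vein stripe count
_SPECIES = {
    "Kalanchoe": dict(a=0.74, b=0.56, p=2.6, hue=0.40, sat=0.50, val=0.60, veins=5, serrate=False),
    "Neem": dict(a=0.86, b=0.32, p=1.8, hue=0.29, sat=0.70, val=0.45, veins=9, serrate=True),
    "Tulsi": dict(a=0.58, b=0.34, p=1.5, hue=0.34, sat=0.60, val=0.55, veins=7, serrate=False),
}


def _leaf_pixels(mask: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    idx = np.flatnonzero(mask)
    return idx[rng.integers(0, len(idx), size=n)]


def render_leaf_image(spec: LeafClassSpec, size: int, rng: np.random.Generator,
                      clutter: float = 0.5, lighting_jitter: float = 0.08) -> np.ndarray:
    """Render one class sample as an 8-bit RGB array (size, size, 3)."""
    sp = _SPECIES[spec.species]

    # HSV canvas: blue-gray cluttered background
    noise = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16.0)
    noise = noise / (np.abs(noise).max() + 1e-9)
    h = np.full((size, size), 0.58)
    s = np.clip(0.10 + 0.05 * clutter * noise, 0.0, 0.17)
    v = np.clip(0.22 + 0.10 * clutter * noise, 0.12, 0.34)

    # leaf silhouette: rotated superellipse with per-image jitter
    yy, xx = np.mgrid[0:size, 0:size]
    cx = (xx / (size - 1) - 0.5 + rng.uniform(-0.02, 0.02)) * 2
    cy = (yy / (size - 1) - 0.5 + rng.uniform(-0.02, 0.02)) * 2
    theta = rng.uniform(-0.09, 0.09)  # near-upright framing, +-5 degrees
    u = cx * np.cos(theta) + cy * np.sin(theta)
    w = -cx * np.sin(theta) + cy * np.cos(theta)
    scale = rng.uniform(0.95, 1.05)
    a, b, p = sp["a"] * scale, sp["b"] * scale, sp["p"]
    if sp["serrate"]:
        ang = np.arctan2(w, u)
        b = b * (1 + 0.10 * np.sin(14 * ang))
    rho = (np.abs(u / a) ** p + np.abs(w / b) ** p) ** (1.0 / p)
    leaf = rho <= 1.0
    if not leaf.any():  # degenerate jitter; recenter deterministically
        leaf = (np.abs(u / sp["a"]) ** p + np.abs(w / sp["b"]) ** p) <= 1.0

    hue0 = sp["hue"] + rng.uniform(-0.02, 0.02)
    sat0, val0 = sp["sat"], sp["val"]
    if spec.disorder == "mildew":
        # diseased foliage also discolors globally: a pale yellow-green cast
        hue0, sat0, val0 = hue0 - 0.035, sat0 - 0.05, min(1.0, val0 + 0.08)
    elif spec.disorder == "halo_spot":
        hue0, sat0, val0 = hue0 - 0.05, sat0 - 0.10, min(1.0, val0 + 0.12)
    h[leaf], s[leaf], v[leaf] = hue0, sat0, val0

    # veins: midrib plus periodic lateral stripes, lighter green
    veins = leaf & ((np.abs(w) < 0.02) | (np.abs(np.sin(sp["veins"] * np.pi * u)) > 0.97))
    vein_hsv = (hue0, max(0.35, sat0 - 0.15), min(1.0, val0 + 0.18))

    d = spec.disorder
    if d in ("chlorosis", "chlorosis_blight"):
        h[leaf], s[leaf], v[leaf] = 0.14, 0.78, 0.75
        if d == "chlorosis_blight":
            margin = leaf & (rho > 0.78)
            h[margin], s[margin], v[margin] = 0.06, 0.70, 0.28
            veins = veins & ~margin
    h[veins], s[veins], v[veins] = vein_hsv

    if d == "web":
        pts = _leaf_pixels(leaf, rng, 2 * 40)
        for k in range(40):
            r0, c0 = divmod(int(pts[2 * k]), size)
            r1, c1 = divmod(int(pts[2 * k + 1]), size)
            rr, cc = draw_line(r0, c0, r1, c1)
            for dr in (0, 1, 2):
                rs = np.clip(rr + dr, 0, size - 1)
                h[rs, cc], s[rs, cc], v[rs, cc] = 0.0, 0.05, 0.85
        for _ in range(rng.integers(6, 10)):
            r0, c0 = divmod(int(_leaf_pixels(leaf, rng, 1)[0]), size)
            rr, cc = draw_disk((r0, c0), max(2, size // 24), shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.05, 0.65, 0.25
    elif d == "ring_spot":
        for _ in range(rng.integers(12, 17)):
            r0, c0 = divmod(int(_leaf_pixels(leaf, rng, 1)[0]), size)
            rad = rng.uniform(0.07, 0.12) * size
            rr, cc = draw_disk((r0, c0), rad, shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.07, 0.65, 0.20  # ring
            rr, cc = draw_disk((r0, c0), 0.65 * rad, shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.08, 0.60, 0.42  # center
    elif d == "mildew":
        for _ in range(rng.integers(10, 14)):
            r0, c0 = divmod(int(_leaf_pixels(leaf, rng, 1)[0]), size)
            dr = rng.uniform(-0.18, 0.18, size=5) * size
            dc = rng.uniform(-0.18, 0.18, size=5) * size
            rr, cc = draw_polygon(np.clip(r0 + dr, 0, size - 1), np.clip(c0 + dc, 0, size - 1))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.13, 0.80, 0.80
        for _ in range(rng.integers(3, 6)):
            r0, c0 = divmod(int(_leaf_pixels(leaf, rng, 1)[0]), size)
            rr, cc = draw_disk((r0, c0), max(3, size // 14), shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.78, 0.30, 0.50
    elif d == "halo_spot":
        for _ in range(rng.integers(8, 12)):
            r0, c0 = divmod(int(_leaf_pixels(leaf, rng, 1)[0]), size)
            rad = rng.uniform(0.05, 0.08) * size
            rr, cc = draw_disk((r0, c0), rad, shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.15, 0.85, 0.80  # yellow halo
            rr, cc = draw_disk((r0, c0), 0.55 * rad, shape=(size, size))
            h[rr, cc], s[rr, cc], v[rr, cc] = 0.08, 0.50, 0.30  # lesion core

    v = np.clip(v * (1 + rng.uniform(-lighting_jitter, lighting_jitter)), 0.0, 1.0)
    rgb = skcolor.hsv2rgb(np.stack([h, s, v], axis=-1))
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def generate_arrays(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Generate the dataset in memory: (images uint8 NxSxSx3, labels int, classes)."""
    specs = class_specs()
    images, labels = [], []
    for ci, spec in enumerate(specs):
        for i in range(config.n_per_class):
            rng = np.random.default_rng([config.seed, ci, i])
            images.append(render_leaf_image(spec, config.image_size, rng,
                                            config.clutter, config.lighting_jitter))
            labels.append(ci)
    return np.stack(images), np.asarray(labels), CLASS_NAMES[:]


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> DatasetManifest:
    """Write the class-per-folder PNG dataset plus manifest.csv; returns the manifest."""
    out_dir = Path(out_dir)
    specs = class_specs()
    records = []
    for ci, spec in enumerate(specs):
        for i in range(config.n_per_class):
            rng = np.random.default_rng([config.seed, ci, i])
            img = render_leaf_image(spec, config.image_size, rng,
                                    config.clutter, config.lighting_jitter)
            rel = f"{spec.name}/{spec.name}_{i:04d}.png"
            save_image(img, out_dir / rel)
            image_id = rel[: -len(".png")]
            records.append(ImageRecord(image_id=image_id, path=str(out_dir / rel),
                                       label=spec.name, parent_id=image_id))
    manifest = DatasetManifest(records=records, metadata={
        "generator": "lsetnet.synthetic",
        "seed": str(config.seed),
        "n_per_class": str(config.n_per_class),
        "image_size": str(config.image_size),
    })
    manifest.validate()
    from .manifest import write_manifest

    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# signature report
# ---------------------------------------------------------------------------

def overlay_mask(rgb: np.ndarray) -> np.ndarray:
    """Boolean mask of disorder-colored pixels (yellow/brown/web-gray/purple)."""
    hsv = skcolor.rgb2hsv(rgb.astype(np.float64) / 255.0)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    yellow = (h >= 0.10) & (h <= 0.22) & (s > 0.35) & (v > 0.40)
    brown = (h < 0.10) & (s > 0.35) & (v < 0.55)
    web = (s < 0.18) & (v > 0.55)
    purple = (h >= 0.60) & (h <= 0.95) & (s > 0.15)
    return yellow | brown | web | purple


def class_signature_report(folder: str | Path) -> pd.DataFrame:
    """Per-class mean hue, brightness and overlay-pixel fraction.

    Used to assert that generated classes are statistically distinct;
    the report is independent of file enumeration order.
    """
    from .manifest import load_image

    folder = Path(folder)
    rows = {}
    for cdir in sorted(d for d in folder.iterdir() if d.is_dir()):
        hues, brightness, fractions = [], [], []
        for p in sorted(cdir.glob("*.png")) + sorted(cdir.glob("*.jpg")):
            rgb = load_image(p)
            hsv = skcolor.rgb2hsv(rgb.astype(np.float64) / 255.0)
            sat = hsv[..., 1]
            leafish = sat > 0.3
            hues.append(hsv[..., 0][leafish].mean() if leafish.any() else np.nan)
            brightness.append(hsv[..., 2].mean())
            fractions.append(overlay_mask(rgb).mean())
        rows[cdir.name] = {
            "mean_hue": float(np.mean(hues)),
            "mean_brightness": float(np.mean(brightness)),
            "overlay_fraction": float(np.mean(fractions)),
            "n_images": len(fractions),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
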