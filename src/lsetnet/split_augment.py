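"""Leakage-free stratified splitting and quota augmentation.

The protocol is split-before-augment: original images are first
partitioned 70/15/15 by stratified sampling within each class, and only
then is each (class, split) cell expanded to its quota (700/150/150 per
class by default, i.e. 1,000 images per class overall) by randomly
parameterized augmentations of that cell's own originals.  An augmented
record's ``parent_id`` always resolves to an original in the same split,
so leakage is impossible by construction and auditable after the fact.

Augmented images can be materialized to disk (auditable counts, exact
byte determinism) or left virtual: a virtual record keeps its parent's
path and is re-rendered on the fly from its seeded transform stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage.transform import AffineTransform, resize as sk_resize, warp

from .manifest import (
    DatasetManifest,
    ImageRecord,
    load_image,
    save_image,
)

logger = logging.getLogger("lsetnet")


@dataclass(frozen=True)
class AugmentPolicy:
    """The augmentation transform family and its parameter ranges.

    Geometric operations use reflection padding; ``ops_per_image``
    transforms are drawn without replacement and composed per sample.
    """

    rotation_deg: float = 40.0
    scale_range: tuple[float, float] = (0.7, 1.3)
    hflip: bool = True
    vflip: bool = True
    translate_px: int = 60
    brightness: tuple[float, float] = (0.6, 1.5)
    contrast: tuple[float, float] = (1.5, 2.3)
    hue_deg: float = 40.0
    zoom: tuple[float, float] = (1.4, 1.8)
    ops_per_image: int = 3

    def op_names(self) -> list[str]:
        ops = ["rotate", "scale", "translate", "brightness", "contrast", "hue", "zoom"]
        if self.hflip:
            ops.append("hflip")
        if self.vflip:
            ops.append("vflip")
        return ops


@dataclass(frozen=True)
class SplitPlan:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    quotas: tuple[int, int, int] = (700, 150, 150)  # train/val/test per class
    seed: int = 42

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")
        if any(q < 1 for q in self.quotas):
            raise ValueError("quotas must be positive integers")


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def stratified_split(manifest: DatasetManifest, plan: SplitPlan) -> DatasetManifest:
    """Assign originals to train/val/test within each class.

    Rounding rule for class sizes not divisible by the ratios: floor for
    val and test, remainder to train.  Deterministic given the plan seed.
    """
    for r in manifest.records:
        if r.origin != "original" or r.split != "unassigned":
            raise ValueError(
                f"stratified_split expects unassigned originals; {r.image_id} is "
                f"{r.origin}/{r.split}"
            )
    classes = manifest.classes
    assignment: dict[str, str] = {}
    for ci, cls in enumerate(classes):
        recs = [r for r in manifest.records if r.label == cls]
        n = len(recs)
        if n < 3:
            raise ValueError(f"class {cls!r} has only {n} images; need >= 3 for a 3-way split")
        n_val = int(np.floor(plan.ratios[1] * n))
        n_test = int(np.floor(plan.ratios[2] * n))
        rng = np.random.default_rng([plan.seed, ci])
        order = rng.permutation(n)
        ids = [recs[i].image_id for i in order]
        for iid in ids[:n_val]:
            assignment[iid] = "val"
        for iid in ids[n_val:n_val + n_test]:
            assignment[iid] = "test"
        for iid in ids[n_val + n_test:]:
            assignment[iid] = "train"
    records = [
        ImageRecord(r.image_id, r.path, r.label, assignment[r.image_id], "original", r.image_id)
        for r in manifest.records
    ]
    out = manifest.with_records(records)
    out.metadata["split_seed"] = str(plan.seed)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# single transforms
# ---------------------------------------------------------------------------

def _warp_reflect(img: np.ndarray, tform: AffineTransform) -> np.ndarray:
    out = warp(img.astype(np.float64), tform.inverse, mode="reflect",
               order=1, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _centered(img: np.ndarray, rotation: float = 0.0, scale: float = 1.0) -> AffineTransform:
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    shift = AffineTransform(translation=(-cx, -cy))
    core = AffineTransform(rotation=rotation, scale=(scale, scale))
    unshift = AffineTransform(translation=(cx, cy))
    return shift + core + unshift


def rotate(img: np.ndarray, degrees: float) -> np.ndarray:
    if degrees == 0.0:
        return img.copy()
    return _warp_reflect(img, _centered(img, rotation=np.deg2rad(degrees)))


def rescale(img: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return img.copy()
    return _warp_reflect(img, _centered(img, scale=factor))


def translate(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    if dx == 0 and dy == 0:
        return img.copy()
    return _warp_reflect(img, AffineTransform(translation=(dx, dy)))


def hflip(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1].copy()


def vflip(img: np.ndarray) -> np.ndarray:
    return img[::-1, :].copy()


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return img.copy()
    return np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(np.uint8)


def adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale deviations from the per-image mean by ``factor``."""
    if factor == 1.0:
        return img.copy()
    x = img.astype(np.float64)
    m = x.mean()
    return np.clip(np.rint(m + factor * (x - m)), 0, 255).astype(np.uint8)


def shift_hue(img: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate hue on the 0-360 degree circle in HSV space."""
    if degrees == 0.0:
        return img.copy()
    hsv = skcolor.rgb2hsv(img.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + degrees / 360.0) % 1.0
    rgb = skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def center_zoom(img: np.ndarray, factor: float) -> np.ndarray:
    """Crop the central 1/factor fraction and resize back to the input size."""
    if factor == 1.0:
        return img.copy()
    h, w = img.shape[:2]
    ch = max(1, int(round(h / factor)))
    cw = max(1, int(round(w / factor)))
    y0 = (h - ch) // 2
    x0 = (w - cw) // 2
    crop = img[y0:y0 + ch, x0:x0 + cw].astype(np.float64)
    out = sk_resize(crop, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_random_augment(image: np.ndarray, policy: AugmentPolicy,
                         rng: np.random.Generator) -> np.ndarray:
    """Compose ``ops_per_image`` randomly parameterized transforms.

    Ops are sampled without replacement from the policy's op list and
    applied in the sampled order; output has the input's size.
    """
    image = np.asarray(image, dtype=np.uint8)
    names = policy.op_names()
    k = min(policy.ops_per_image, len(names))
    chosen = rng.choice(len(names), size=k, replace=False)
    out = image
    for idx in chosen:
        op = names[idx]
        if op == "rotate":
            out = rotate(out, rng.uniform(-policy.rotation_deg, policy.rotation_deg))
        elif op == "scale":
            out = rescale(out, rng.uniform(*policy.scale_range))
        elif op == "translate":
            t = policy.translate_px
            out = translate(out, int(rng.integers(-t, t + 1)), int(rng.integers(-t, t + 1)))
        elif op == "brightness":
            out = adjust_brightness(out, rng.uniform(*policy.brightness))
        elif op == "contrast":
            out = adjust_contrast(out, rng.uniform(*policy.contrast))
        elif op == "hue":
            out = shift_hue(out, rng.uniform(-policy.hue_deg, policy.hue_deg))
        elif op == "zoom":
            out = center_zoom(out, rng.uniform(*policy.zoom))
        elif op == "hflip":
            out = hflip(out) if rng.random() < 0.5 else out
        elif op == "vflip":
            out = vflip(out) if rng.random() < 0.5 else out
    return out


# ---------------------------------------------------------------------------
# quota augmentation
# ---------------------------------------------------------------------------

_SPLIT_INDEX = {"train": 0, "val": 1, "test": 2}


def augment_rng(seed: int, class_index: int, split: str, j: int) -> np.random.Generator:
    """The seeded stream for the j-th augmented sample of a (class, split) cell."""
    return np.random.default_rng([seed, class_index, _SPLIT_INDEX[split], j])


def augment_to_quota(manifest: DatasetManifest, plan: SplitPlan, policy: AugmentPolicy,
                     out_dir: str | Path | None = None,
                     loader=load_image) -> DatasetManifest:
    """Expand every (class, split) cell to its quota with augmented copies.

    Originals are always retained; augmented copies are generated
    round-robin over the cell's originals until the quota is met exactly.
    A cell with more originals than its quota is a hard error (images are
    never discarded silently).  With ``out_dir`` set, augmented PNGs are
    written to ``out_dir/<class>/``; otherwise records are virtual
    (path = parent path) and can be rendered on the fly with
    :func:`render_augmented`.
    """
    classes = manifest.classes
    new_records = list(manifest.records)
    for ci, cls in enumerate(classes):
        for split, quota in zip(("train", "val", "test"), plan.quotas):
            originals = sorted(manifest.subset(split=split, label=cls, origin="original"),
                               key=lambda r: r.image_id)
            if not originals:
                raise ValueError(f"empty cell: class {cls!r} split {split!r}")
            if len(originals) > quota:
                raise ValueError(
                    f"class {cls!r} split {split!r} has {len(originals)} originals, "
                    f"more than the quota {quota}; refusing to discard images"
                )
            deficit = quota - len(originals)
            for j in range(deficit):
                parent = originals[j % len(originals)]
                image_id = f"{parent.image_id}_aug{j:04d}"
                if out_dir is not None:
                    rng = augment_rng(plan.seed, ci, split, j)
                    img = apply_random_augment(loader(parent.path), policy, rng)
                    rel = f"{cls}/{Path(parent.path).stem}_aug{j:04d}.png"
                    path = str(Path(out_dir) / rel)
                    save_image(img, path)
                else:
                    path = parent.path
                new_records.append(ImageRecord(
                    image_id=image_id, path=path, label=cls, split=split,
                    origin="augmented", parent_id=parent.image_id,
                ))
    out = manifest.with_records(new_records)
    out.metadata["augment_seed"] = str(plan.seed)
    out.metadata["materialized"] = str(out_dir is not None)
    out.validate()
    return out


def render_augmented(record: ImageRecord, manifest: DatasetManifest, plan: SplitPlan,
                     policy: AugmentPolicy, loader=load_image) -> np.ndarray:
    """Re-render a virtual augmented record from its seeded transform stream."""
    if record.origin != "augmented":
        return loader(record.path)
    ci = manifest.classes.index(record.label)
    j = int(record.image_id.rsplit("_aug", 1)[1])
    rng = augment_rng(plan.seed, ci, record.split, j)
    return apply_random_augment(loader(record.path), policy, rng)


# ---------------------------------------------------------------------------
# leakage audit
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    passed: bool
    violations: list[str]
    cell_counts: dict[tuple[str, str], int]

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"leakage audit: {status} ({len(self.violations)} violations)"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


def audit_leakage(manifest: DatasetManifest, plan: SplitPlan | None = None) -> AuditReport:
    """Verify split disjointness, parent-split consistency, and quotas.

    Order-invariant: the verdict depends only on the record set.  When a
    plan is supplied, per-(class, split) counts are checked against its
    quotas as well.
    """
    violations: list[str] = []
    by_id: dict[str, ImageRecord] = {}
    for r in manifest.records:
        if r.image_id in by_id:
            violations.append(f"duplicate image id {r.image_id}")
        by_id[r.image_id] = r

    for r in manifest.records:
        if r.split not in ("train", "val", "test"):
            violations.append(f"{r.image_id}: unassigned split")
        if r.origin == "augmented":
            parent = by_id.get(r.parent_id)
            if parent is None:
                violations.append(f"{r.image_id}: parent {r.parent_id} not in manifest")
            elif parent.origin != "original":
                violations.append(f"{r.image_id}: parent {r.parent_id} is not an original")
            elif parent.split != r.split:
                violations.append(
                    f"{r.image_id}: split {r.split} but parent {r.parent_id} "
                    f"is in split {parent.split}"
                )

    cells: dict[tuple[str, str], int] = {}
    for r in manifest.records:
        cells[(r.label, r.split)] = cells.get((r.label, r.split), 0) + 1
    if plan is not None:
        for cls in manifest.classes:
            for split, quota in zip(("train", "val", "test"), plan.quotas):
                got = cells.get((cls, split), 0)
                if got != quota:
                    violations.append(f"class {cls!r} split {split!r}: {got} != quota {quota}")

    violations = sorted(violations)
    return AuditReport(passed=not violations, violations=violations, cell_counts=cells)
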