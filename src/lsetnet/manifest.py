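"""Dataset manifests and image-folder IO.

A :class:`DatasetManifest` is the single currency every other module
consumes: a flat table of image records carrying class label, split
assignment and augmentation provenance (``parent_id``), which is what
makes train/val/test leakage auditable.  Manifests serialize to plain
UTF-8 CSV with a header row so audits can be eyeballed and diffed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError

logger = logging.getLogger("lsetnet")

SPLITS = ("train", "val", "test", "unassigned")
ORIGINS = ("original", "augmented")

_COLUMNS = ["image_id", "path", "label", "split", "origin", "parent_id"]


class ManifestError(ValueError):
    """Raised for malformed manifests or invariant violations."""


class LeakageError(RuntimeError):
    """Raised when an operation would mix information across splits."""


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    path: str
    label: str
    split: str = "unassigned"
    origin: str = "original"
    parent_id: str = ""

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ManifestError(f"invalid split {self.split!r}")
        if self.origin not in ORIGINS:
            raise ManifestError(f"invalid origin {self.origin!r}")
        if self.origin == "original" and self.parent_id not in ("", self.image_id):
            raise ManifestError("original records must be their own parent")

    @property
    def parent(self) -> str:
        """Identifier of the original this record derives from (self for originals)."""
        return self.parent_id or self.image_id


@dataclass
class DatasetManifest:
    records: list[ImageRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        """Sorted set of labels present; index order defines the label mapping."""
        return sorted({r.label for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate image ids: {dupes[:5]}")
        by_id = {r.image_id: r for r in self.records}
        for r in self.records:
            if r.origin == "augmented":
                parent = by_id.get(r.parent_id)
                if parent is None:
                    raise ManifestError(f"{r.image_id}: parent {r.parent_id!r} missing")
                if parent.split != r.split:
                    raise ManifestError(
                        f"{r.image_id}: split {r.split} differs from parent split {parent.split}"
                    )

    def subset(self, split: str | None = None, label: str | None = None,
               origin: str | None = None) -> list[ImageRecord]:
        out = self.records
        if split is not None:
            out = [r for r in out if r.split == split]
        if label is not None:
            out = [r for r in out if r.label == label]
        if origin is not None:
            out = [r for r in out if r.origin == origin]
        return out

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.split] = out.get(r.split, 0) + 1
        return out

    def with_records(self, records: list[ImageRecord]) -> "DatasetManifest":
        return DatasetManifest(records=records, metadata=dict(self.metadata))


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as 8-bit RGB (H, W, 3).

    EXIF orientation is normalized; grayscale is replicated to three
    channels; an alpha channel is discarded.
    """
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def save_image(array: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB array as PNG/JPEG according to the suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)


def scan_image_folder(root: str | Path) -> DatasetManifest:
    """Build a manifest from a class-per-subdirectory image folder.

    Records are ordered lexicographically by path; undecodable files are
    skipped with a warning and counted in the manifest metadata.  The
    scan is a pure function of the directory contents.
    """
    root = Path(root)
    if not root.is_dir():
        raise ManifestError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ManifestError(f"dataset root {root} contains no class subdirectories")

    records: list[ImageRecord] = []
    skipped = 0
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir()
                       if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS)
        n_before = len(records)
        for p in files:
            try:
                with Image.open(p) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError):
                logger.warning("skipping undecodable image %s", p)
                skipped += 1
                continue
            image_id = str(p.relative_to(root).with_suffix("")).replace("\\", "/")
            records.append(ImageRecord(
                image_id=image_id, path=str(p), label=cdir.name,
                split="unassigned", origin="original", parent_id=image_id,
            ))
        if len(records) == n_before:
            logger.warning("class folder %s contains no decodable images", cdir)

    manifest = DatasetManifest(records=records,
                               metadata={"root": str(root), "skipped": str(skipped)})
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# manifest CSV round-trip
# ---------------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest as UTF-8 CSV; metadata rides in '#key=value' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key, value in sorted(manifest.metadata.items()):
            fh.write(f"#{key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in manifest.records:
            writer.writerow([r.image_id, r.path, r.label, r.split, r.origin, r.parent_id])


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    metadata: dict[str, str] = {}
    records: list[ImageRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_start = 0
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            metadata[key] = value
            data_start += 1
        else:
            break
    reader = csv.reader(lines[data_start:])
    try:
        header = next(reader)
    except StopIteration:
        raise ManifestError(f"{path}: empty manifest file") from None
    if header != _COLUMNS:
        raise ManifestError(f"{path}: unexpected header {header}")
    for i, row in enumerate(reader, start=data_start + 2):
        if len(row) != len(_COLUMNS):
            raise ManifestError(f"{path}: malformed row {i}: {row}")
        try:
            records.append(ImageRecord(*row))
        except ManifestError as exc:
            raise ManifestError(f"{path}: row {i}: {exc}") from None
    manifest = DatasetManifest(records=records, metadata=metadata)
    manifest.validate()
    return manifest
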