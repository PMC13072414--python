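"""Dataset I/O, group-aware splitting, and imbalance-correcting weights.

On disk a dataset is a tree of identity folders named ``<index>.<id>``
(e.g. ``001.bm``) holding cropped face images, optionally accompanied by
YOLO-format annotation text files (one normalized ``class cx cy w h`` line
per face) and a CSV manifest carrying the source-group id of every image.
Group ids identify the video (or capture event) an image came from; the
train/test split never places two images of the same group on opposite
sides, which is the anti-leakage rule for re-identification data where
consecutive frames are near-duplicates.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BoxAnnotation:
    """One normalized YOLO box: class id plus center/size in [0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def to_pixels(self, image_size: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open 0-based pixel box (x0, y0, x1, y1): floor min corner, ceil max."""
        width, height = image_size
        x0 = int(np.floor((self.cx - self.w / 2) * width))
        y0 = int(np.floor((self.cy - self.h / 2) * height))
        x1 = int(np.ceil((self.cx + self.w / 2) * width))
        y1 = int(np.ceil((self.cy + self.h / 2) * height))
        x0, x1 = max(x0, 0), min(x1, width)
        y0, y1 = max(y0, 0), min(y1, height)
        return (x0, y0, x1, y1)

    def to_line(self) -> str:
        return f"{self.class_id} {self.cx:.6f} {self.cy:.6f} {self.w:.6f} {self.h:.6f}"


@dataclass
class LabeledDataset:
    """Image records with identity labels and source-group ids.

    ``images`` holds either in-memory uint8 (H, W, 3) arrays or file paths
    that are loaded lazily.  ``class_names`` maps contiguous label indices
    (0..K-1) to identity strings.
    """

    images: list
    labels: np.ndarray
    groups: np.ndarray
    class_names: list[str]
    boxes: list | None = None
    masks: list | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        self.groups = np.asarray(self.groups, dtype=np.intp)
        if len(self.images) != len(self.labels) or len(self.labels) != len(self.groups):
            raise ValueError("images, labels and groups must have equal length")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("label indices must be contiguous and within class_names")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def get_image(self, i: int) -> np.ndarray:
        img = self.images[i]
        if isinstance(img, (str, Path)):
            with Image.open(img) as im:
                return np.asarray(im.convert("RGB"))
        return img

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return LabeledDataset(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            groups=self.groups[idx],
            class_names=list(self.class_names),
            boxes=[self.boxes[i] for i in idx] if self.boxes is not None else None,
            masks=[self.masks[i] for i in idx] if self.masks is not None else None,
        )


# ---------------------------------------------------------------------------
# YOLO annotations and face crops
# ---------------------------------------------------------------------------


class AnnotationError(ValueError):
    pass


def read_yolo_annotation(
    text: str, image_size: tuple[int, int]
) -> list[tuple[BoxAnnotation, tuple[int, int, int, int]]]:
    """Parse YOLO-format lines into (annotation, pixel box) pairs.

    ``image_size`` is (width, height).  Raises :class:`AnnotationError` naming
    the offending line for malformed input, and for values outside [0, 1].
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise AnnotationError(f"line {lineno}: expected 5 fields, got {len(fields)}")
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-numeric field ({exc})") from None
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"line {lineno}: {name}={v} outside [0, 1]")
        ann = BoxAnnotation(class_id, cx, cy, w, h)
        out.append((ann, ann.to_pixels(image_size)))
    return out


def write_yolo_annotation(annotations: list[BoxAnnotation]) -> str:
    return "\n".join(a.to_line() for a in annotations) + "\n"


def crop_face(image: np.ndarray, pixel_box: tuple[int, int, int, int], pad_frac: float = 0.0) -> np.ndarray:
    """Crop a (padded) face box out of an image, clipping to bounds."""
    if pad_frac < 0:
        raise ValueError("pad_frac must be >= 0")
    x0, y0, x1, y1 = pixel_box
    px = int(round(pad_frac * (x1 - x0)))
    py = int(round(pad_frac * (y1 - y0)))
    h, w = image.shape[:2]
    x0, x1 = max(x0 - px, 0), min(x1 + px, w)
    y0, y1 = max(y0 - py, 0), min(y1 + py, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate crop box after clipping: {(x0, y0, x1, y1)}")
    return image[y0:y1, x0:x1]


# ---------------------------------------------------------------------------
# group-aware split
# ---------------------------------------------------------------------------


def _group_key(seed: int, group_id: int) -> int:
    """Order-independent pseudo-random key for a group (stable across runs)."""
    digest = hashlib.sha256(f"{seed}:{group_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def split_dataset(
    ds: LabeledDataset, test_fraction: float, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Group-aware train/test split.

    No group id lands on both sides.  Per identity, whole groups are moved to
    the test side (in an order keyed by a seed-dependent hash of the group id,
    so the split is invariant to record order) until the identity's test share
    reaches the target; at least one group always stays in train, and an
    identity with a single group goes entirely to train with a warning.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    test_groups: set[int] = set()
    for label in range(ds.n_classes):
        idx = np.flatnonzero(ds.labels == label)
        if idx.size == 0:
            continue
        gids, counts = np.unique(ds.groups[idx], return_counts=True)
        if gids.size < 2:
            warnings.warn(
                f"identity '{ds.class_names[label]}' has a single source group; "
                "all its images go to the training split"
            )
            continue
        order = np.argsort([_group_key(seed, int(g)) for g in gids])
        target = test_fraction * counts.sum()
        taken = 0
        chosen: list[int] = []
        for j in order:
            if taken >= target or len(chosen) >= gids.size - 1:
                break
            chosen.append(int(gids[j]))
            taken += counts[j]
        if not chosen:
            # the target rounded to zero: still give the identity a test group
            chosen.append(int(gids[order[0]]))
        test_groups.update(chosen)
    in_test = np.isin(ds.groups, sorted(test_groups))
    return ds.subset(np.flatnonzero(~in_test)), ds.subset(np.flatnonzero(in_test))


# ---------------------------------------------------------------------------
# sampling weights
# ---------------------------------------------------------------------------


def class_weights(counts) -> np.ndarray:
    """Per-class weights inversely proportional to class counts, summing to 1."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    w = 1.0 / counts
    return w / w.sum()


def sample_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-sample draw probabilities that balance classes in expectation.

    Each sample's weight is inversely proportional to its class count, so the
    probability of drawing class c is count_c * (1/count_c) / Z = 1/K: batches
    drawn with replacement under these weights are class-balanced.
    """
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    w = np.where(counts[labels] > 0, 1.0 / counts[labels], 0.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# identity-folder trees
# ---------------------------------------------------------------------------


def scan_identity_folders(root) -> LabeledDataset:
    """Read an identity-folder tree (``<index>.<id>`` directories of images).

    Class indices follow sorted folder names.  Group ids are read from a
    ``manifest.csv`` (columns path, identity, group_id) when present next to
    the folders; otherwise each folder becomes one group, with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise ValueError(f"no identity folders found under {root}")
    manifest = None
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        df = pd.read_csv(manifest_path)
        manifest = {str(p): int(g) for p, g in zip(df["path"], df["group_id"])}
    else:
        warnings.warn("no manifest.csv found; assigning one group per identity folder")
    per_folder = {
        f: [p for p in sorted(f.iterdir()) if p.suffix.lower() in IMAGE_EXTENSIONS] for f in folders
    }
    folders = [f for f in folders if per_folder[f]]  # e.g. a "labels" mirror holds no images
    if not folders:
        raise ValueError(f"no images found under {root}")
    images: list = []
    labels: list[int] = []
    groups: list[int] = []
    class_names = [f.name for f in folders]
    for label, folder in enumerate(folders):
        for img_path in per_folder[folder]:
            images.append(img_path)
            labels.append(label)
            if manifest is not None:
                rel = str(img_path.relative_to(root))
                groups.append(manifest.get(rel, -1))
            else:
                groups.append(label)
    return LabeledDataset(images=images, labels=np.array(labels), groups=np.array(groups), class_names=class_names)
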