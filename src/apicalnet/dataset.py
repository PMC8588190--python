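"""Labeled tooth-image database: augmentation, balancing, resizing, splitting.

Clinic archives of single-tooth crops are heavily imbalanced (far more
normal teeth than apical lesions).  The builder here balances the two
classes to a common target -- augmenting the minority with seeded
flip/zoom/rotation/translation/contrast/brightness transforms and
subsampling the majority -- standardizes resolution, and partitions the
result 70/30 by a seeded permutation.

Two pipeline orders are exposed.  The default splits the raw database
first and augments only the training side, so augmented copies of one
crop can never land in both partitions.  ``order="balance_first"``
reproduces the published arithmetic instead (balance the whole database
to the target, then split), at the cost of possible augmentation
leakage across the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

LABELS = ("normal", "lesion")


@dataclass(frozen=True)
class LabeledSample:
    """One grayscale crop with its class label and provenance tag."""

    image: np.ndarray
    label: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


class LabeledDataset:
    """Ordered collection of labeled samples."""

    def __init__(self, samples: Sequence[LabeledSample]):
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> LabeledSample:
        return self.samples[i]

    def __iter__(self):
        return iter(self.samples)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices])

    def by_label(self, label: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.label == label]


@dataclass(frozen=True)
class AugmentationSpec:
    """Which random transforms augmentation may draw, and their ranges.

    The ranges are mild on purpose: a transform that moved the apex out
    of frame or inverted contrast would no longer carry its label.
    """

    ops: tuple[str, ...] = (
        "horizontal_flip",
        "vertical_flip",
        "zoom",
        "rotation",
        "translation",
        "contrast",
        "brightness",
    )
    zoom_range: float = 0.10          # fraction, +/-
    rotation_range: float = 10.0      # degrees, +/-
    translation_range: int = 10       # pixels, +/- per axis
    contrast_range: float = 0.20      # fraction, +/-
    brightness_range: float = 20.0    # intensity units, +/-
    seed: int = 0

    _KNOWN = (
        "horizontal_flip", "vertical_flip", "zoom", "rotation",
        "translation", "contrast", "brightness",
    )

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in self._KNOWN:
                raise ValueError(f"unknown augmentation op {op!r}")
        for name in ("zoom_range", "rotation_range", "translation_range",
                     "contrast_range", "brightness_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# -- deterministic transform primitives (randomized draws build on these) --

def flip_horizontal(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1]


def flip_vertical(img: np.ndarray) -> np.ndarray:
    return img[::-1, :]


def adjust_brightness(img: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(np.rint(img.astype(np.float64) + delta), 0, 255).astype(np.uint8)


def adjust_contrast(img: np.ndarray, factor_delta: float) -> np.ndarray:
    """Scale deviations from the mean by (1 + factor_delta)."""
    x = img.astype(np.float64)
    out = x.mean() + (x - x.mean()) * (1.0 + factor_delta)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _apply_zoom(img: np.ndarray, factor: float) -> np.ndarray:
    h, w = img.shape
    zh, zw = max(1, round(h * factor)), max(1, round(w * factor))
    zoomed = _sk_resize(img.astype(np.float64), (zh, zw), order=1,
                        preserve_range=True, anti_aliasing=zh < h)
    out = np.zeros((h, w))
    if factor >= 1.0:  # center crop
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out = zoomed[r0 : r0 + h, c0 : c0 + w]
    else:  # center pad
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out[r0 : r0 + zh, c0 : c0 + zw] = zoomed
    return out


def _apply_translation(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def _transform(img: np.ndarray, spec: AugmentationSpec,
               rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float64)
    if "horizontal_flip" in spec.ops and rng.random() < 0.5:
        out = flip_horizontal(out)
    if "vertical_flip" in spec.ops and rng.random() < 0.5:
        out = flip_vertical(out)
    if "rotation" in spec.ops and spec.rotation_range > 0:
        angle = rng.uniform(-spec.rotation_range, spec.rotation_range)
        out = _sk_rotate(out, angle, resize=False, order=1, mode="constant",
                         cval=0.0, preserve_range=True)
    if "zoom" in spec.ops and spec.zoom_range > 0:
        out = _apply_zoom(out, 1.0 + rng.uniform(-spec.zoom_range, spec.zoom_range))
    if "translation" in spec.ops and spec.translation_range > 0:
        dr = int(rng.integers(-spec.translation_range, spec.translation_range + 1))
        dc = int(rng.integers(-spec.translation_range, spec.translation_range + 1))
        out = _apply_translation(out, dr, dc)
    if "contrast" in spec.ops and spec.contrast_range > 0:
        c = rng.uniform(-spec.contrast_range, spec.contrast_range)
        out = out.mean() + (out - out.mean()) * (1.0 + c)
    if "brightness" in spec.ops and spec.brightness_range > 0:
        out = out + rng.uniform(-spec.brightness_range, spec.brightness_range)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_sample(sample: LabeledSample, spec: AugmentationSpec,
                   k: int) -> list[LabeledSample]:
    """Produce ``k`` label-preserving random variants of one sample."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 0 and not spec.ops:
        raise ValueError("cannot augment with an empty op set")
    rng = np.random.default_rng(spec.seed)
    out = []
    for j in range(k):
        img = _transform(sample.image, spec, rng)
        out.append(LabeledSample(img, sample.label,
                                 provenance=f"{sample.provenance}+aug{j}"))
    return out


def balance_classes(dataset: LabeledDataset, target_per_class: int,
                    spec: AugmentationSpec) -> LabeledDataset:
    """Equalize both classes at ``target_per_class`` samples.

    Classes below the target are augmented round-robin over their
    originals (in index order); classes above it are subsampled without
    replacement by the spec's seed.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    kept: list[LabeledSample] = []
    for label in LABELS:
        idx = dataset.by_label(label)
        if not idx:
            raise ValueError(f"class {label!r} is empty; cannot balance")
        if len(idx) >= target_per_class:
            chosen = rng.choice(len(idx), size=target_per_class, replace=False)
            kept.extend(dataset.samples[idx[i]] for i in sorted(chosen))
        else:
            kept.extend(dataset.samples[i] for i in idx)
            need = target_per_class - len(idx)
            aug_rng = np.random.default_rng(spec.seed + 1)
            for j in range(need):
                src = dataset.samples[idx[j % len(idx)]]
                img = _transform(src.image, spec, aug_rng)
                kept.append(LabeledSample(img, label,
                                          provenance=f"{src.provenance}+bal{j}"))
    return LabeledDataset(kept)


def standardize_resolution(dataset: LabeledDataset, height: int = 200,
                           width: int = 100) -> LabeledDataset:
    """Resample every image to height x width with bilinear interpolation."""
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be positive")
    out = []
    for s in dataset:
        if s.image.shape == (height, width):
            out.append(s)
            continue
        img = _sk_resize(s.image.astype(np.float64), (height, width), order=1,
                         preserve_range=True, anti_aliasing=True)
        out.append(replace(s, image=np.clip(np.rint(img), 0, 255).astype(np.uint8)))
    return LabeledDataset(out)


@dataclass(frozen=True)
class SplitIndex:
    """Reproducible train/test partition of sample indices."""

    train_val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    train_frac: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_val_ids) & set(self.test_ids):
            raise ValueError("partitions overlap")


def split_dataset(dataset: LabeledDataset, train_frac: float = 0.7,
                  seed: int = 0) -> SplitIndex:
    """Seeded 70/30-style partition with floor rounding of the train size."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(train_frac * n)
    return SplitIndex(tuple(int(i) for i in perm[:n_train]),
                      tuple(int(i) for i in perm[n_train:]),
                      train_frac, seed)


def build_database(
    raw: LabeledDataset,
    target_per_class: int = 230,
    aug: AugmentationSpec | None = None,
    resolution: tuple[int, int] = (200, 100),
    train_frac: float = 0.7,
    seed: int = 0,
    order: str = "split_first",
) -> tuple[LabeledDataset, LabeledDataset, SplitIndex]:
    """Assemble (train_val, test) sets from a raw labeled database.

    ``order="split_first"`` (default) partitions the raw crops and
    balances only the training side, so no augmented copy of a training
    crop can appear in the test set.  ``order="balance_first"`` follows
    the published arithmetic: balance the whole database to
    2 x target_per_class, then split it.
    """
    aug = aug or AugmentationSpec(seed=seed)
    raw = standardize_resolution(raw, *resolution)
    if order == "balance_first":
        balanced = balance_classes(raw, target_per_class, aug)
        split = split_dataset(balanced, train_frac, seed)
        return balanced.subset(split.train_val_ids), balanced.subset(split.test_ids), split
    if order != "split_first":
        raise ValueError(f"unknown order {order!r}")
    split = split_dataset(raw, train_frac, seed)
    train = balance_classes(raw.subset(split.train_val_ids), target_per_class, aug)
    return train, raw.subset(split.test_ids), split


# ---------------------------------------------------------------------------
# disk layout: root/normal/*.png, root/lesion/*.png; split file lists paths

def save_dataset(dataset: LabeledDataset, root: str | Path) -> None:
    from .images import write_gray

    root = Path(root)
    counters = {label: 0 for label in LABELS}
    for s in dataset:
        d = root / s.label
        d.mkdir(parents=True, exist_ok=True)
        write_gray(s.image, d / f"{s.label}_{counters[s.label]:04d}.png")
        counters[s.label] += 1


def load_dataset(root: str | Path) -> LabeledDataset:
    from .images import read_gray

    root = Path(root)
    samples = []
    for label in LABELS:
        d = root / label
        if not d.is_dir():
            continue
        for p in sorted(d.glob("*.png")):
            samples.append(LabeledSample(read_gray(p), label, provenance=str(p)))
    return LabeledDataset(samples)


def save_split(split: SplitIndex, path: str | Path) -> None:
    lines = [f"train_frac\t{split.train_frac}", f"seed\t{split.seed}"]
    lines += [f"train\t{i}" for i in split.train_val_ids]
    lines += [f"test\t{i}" for i in split.test_ids]
    Path(path).write_text("\n".join(lines) + "\n")


def load_split(path: str | Path) -> SplitIndex:
    train, test = [], []
    frac, seed = 0.7, 0
    for line in Path(path).read_text().splitlines():
        kind, value = line.split("\t")
        if kind == "train_frac":
            frac = float(value)
        elif kind == "seed":
            seed = int(value)
        elif kind == "train":
            train.append(int(value))
        elif kind == "test":
            test.append(int(value))
    return SplitIndex(tuple(train), tuple(test), frac, seed)
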