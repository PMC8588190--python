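"""Projection-based tooth cropping.

A binarized film has bright teeth separated by dark seams, so the
per-column sum of the binary image dips to (near) zero exactly at the
seams.  Cutting recursively at the minimum-sum column splits the film
into single-tooth crops; a cut whose output would be narrower than a
quarter of its input is rejected and the input kept whole, which stops
the recursion once pieces hold a single tooth.  Films are first
rotation-corrected so the seams run vertically, and crops can be
retouched by zeroing columns outside the target band.

Coordinate conventions: columns are 0-based and intervals are inclusive
on both ends; the two pieces of a cut share the cut column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .preprocessing import binarize, iterative_threshold

DEFAULT_EDGE_MARGIN_FRAC = 1.0 / 8.0
DEFAULT_MIN_WIDTH_FRAC = 1.0 / 4.0


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-column totals of a binary image."""

    column_sums: np.ndarray
    width: int

    def __post_init__(self) -> None:
        if len(self.column_sums) != self.width:
            raise ValueError("column_sums length must equal width")


@dataclass(frozen=True)
class CutLine:
    column: int
    sum_at_cut: float


@dataclass(frozen=True)
class ToothCrop:
    """A single-tooth subimage cut from a parent film.

    ``source_interval`` is the inclusive column interval in the parent;
    ``mask_band`` the inclusive column interval (in crop coordinates)
    kept by retouching; ``depth`` the recursion depth of the cut tree.
    """

    image: np.ndarray
    source_interval: tuple[int, int]
    mask_band: tuple[int, int]
    depth: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.source_interval
        if hi - lo + 1 != self.image.shape[1]:
            raise ValueError("source_interval width must equal image width")
        b0, b1 = self.mask_band
        if not (0 <= b0 <= b1 < self.image.shape[1]):
            raise ValueError("mask_band must lie within the crop")


def vertical_projection(image: np.ndarray) -> ProjectionProfile:
    """Sum the pixel values of each column."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return ProjectionProfile(arr.sum(axis=0, dtype=np.int64), arr.shape[1])


def find_cut_line(
    profile: ProjectionProfile, edge_margin_frac: float = DEFAULT_EDGE_MARGIN_FRAC
) -> CutLine:
    """Column with the smallest projection sum, away from the film borders.

    The search is restricted to columns in [ceil(m*W), W - ceil(m*W))
    because the dark film borders would otherwise always win.  Whole
    runs of columns commonly tie at the minimum (every seam is fully
    dark after binarization); the cut goes to the middle of the tied
    run nearest the piece center -- the physical middle of that seam --
    with remaining ties leftmost.  Centering keeps the recursion
    balanced instead of always peeling at the leftmost seam.
    """
    w = profile.width
    margin = ceil(edge_margin_frac * w)
    lo, hi = margin, w - margin
    if hi - lo < 1:
        raise ValueError(
            f"empty search region for width {w} with margin fraction {edge_margin_frac}"
        )
    segment = profile.column_sums[lo:hi]
    minimum = segment.min()
    candidates = lo + np.flatnonzero(segment == minimum)
    # group tied columns into contiguous runs and cut mid-run
    splits = np.flatnonzero(np.diff(candidates) > 1) + 1
    runs = np.split(candidates, splits)
    centers = [int(run[(len(run) - 1) // 2]) for run in runs]
    center = (w - 1) / 2.0
    col = min(centers, key=lambda c: (abs(c - center), c))
    return CutLine(col, float(profile.column_sums[col]))


def vertical_cut(
    image: np.ndarray, cut: CutLine
) -> tuple[ToothCrop, ToothCrop]:
    """Split at the cut line; both pieces keep the cut column."""
    w = image.shape[1]
    if not (0 < cut.column < w - 1):
        raise ValueError(f"cut column {cut.column} is at the border of width {w}")
    left = image[:, : cut.column + 1]
    right = image[:, cut.column :]
    return (
        ToothCrop(left, (0, cut.column), (0, left.shape[1] - 1)),
        ToothCrop(right, (cut.column, w - 1), (0, right.shape[1] - 1)),
    )


def recursive_cut(
    film: np.ndarray,
    binary: np.ndarray,
    min_width_frac: float = DEFAULT_MIN_WIDTH_FRAC,
    edge_margin_frac: float = DEFAULT_EDGE_MARGIN_FRAC,
    seam_frac: float = 0.02,
) -> list[ToothCrop]:
    """Cut a film into single-tooth crops, left to right.

    Each piece is cut at its own minimum-sum column.  A cut is discarded
    (and the piece emitted whole) when either output would be narrower
    than ``min_width_frac`` of that piece's width, or when the cut
    column is not actually dark: cutting lines live on interdental
    seams, which binarize to (near) zero, so a minimum-sum column still
    brighter than ``seam_frac`` of the piece's tallest column means the
    piece holds no interior seam -- typically a single tooth whose
    darkest interior column is a radiolucent lesion, not a boundary.
    Grayscale crops are taken from ``film`` at the binary-derived
    intervals.
    """
    film = np.asarray(film)
    binary = np.asarray(binary)
    if film.shape != binary.shape:
        raise ValueError(f"film {film.shape} and binary {binary.shape} must match")

    crops: list[ToothCrop] = []

    def emit(lo: int, hi: int, depth: int) -> None:
        piece = film[:, lo : hi + 1]
        crops.append(ToothCrop(piece, (lo, hi), (0, hi - lo), depth))

    def rec(lo: int, hi: int, depth: int) -> None:
        w = hi - lo + 1
        if w < 4:
            emit(lo, hi, depth)
            return
        profile = vertical_projection(binary[:, lo : hi + 1])
        try:
            cut = find_cut_line(profile, edge_margin_frac)
        except ValueError:
            emit(lo, hi, depth)
            return
        peak = float(profile.column_sums.max())
        if peak <= 0 or cut.sum_at_cut > seam_frac * peak:
            emit(lo, hi, depth)
            return
        left_w = cut.column + 1
        right_w = w - cut.column
        if left_w < min_width_frac * w or right_w < min_width_frac * w:
            emit(lo, hi, depth)
            return
        rec(lo, lo + cut.column, depth + 1)
        rec(lo + cut.column, hi, depth + 1)

    rec(0, film.shape[1] - 1, 0)
    return crops


def retouch(crop: ToothCrop, band: tuple[int, int]) -> ToothCrop:
    """Zero every column outside the band; columns inside are untouched."""
    b0, b1 = band
    w = crop.image.shape[1]
    if not (0 <= b0 <= b1 < w):
        raise ValueError(f"band {band} is empty or outside width {w}")
    masked = crop.image.copy()
    masked[:, :b0] = 0
    masked[:, b1 + 1 :] = 0
    return replace(crop, image=masked, mask_band=(b0, b1))


def content_band(binary_crop: np.ndarray) -> tuple[int, int]:
    """Inclusive column interval spanning the bright content of a crop.

    Falls back to the full width when the crop is entirely dark.
    """
    cols = np.flatnonzero(np.asarray(binary_crop).sum(axis=0))
    if cols.size == 0:
        return (0, binary_crop.shape[1] - 1)
    return (int(cols[0]), int(cols[-1]))


def _valley_score(binary: np.ndarray) -> tuple[float, int]:
    """(minimum column sum, -count at minimum) inside the content band.

    Scored only between the first and last bright columns: rotation
    shifts content and would otherwise expose empty border columns as
    spurious zero-depth valleys.  The count term prefers the angle where
    the seams are most nearly vertical (widest run at the minimum).
    """
    profile = vertical_projection(binary)
    cols = np.flatnonzero(profile.column_sums)
    if cols.size < 3:
        return (0.0, 0)
    inset = max(2, (cols[-1] - cols[0]) // 16)
    segment = profile.column_sums[cols[0] + inset : cols[-1] + 1 - inset]
    if segment.size == 0:
        segment = profile.column_sums[cols[0] : cols[-1] + 1]
    minimum = segment.min()
    return (float(minimum), -int((segment == minimum).sum()))


def rotation_correct(
    image: np.ndarray,
    angle_range_deg: float = 10.0,
    step_deg: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Rotate the film so interdental seams run vertically.

    Every candidate angle in [-range, +range] (inclusive, ``step_deg``
    apart) is scored by the binarized projection valley inside the
    content band -- the seams are vertical exactly when that valley is
    deepest (and, at equal depth, widest).  Remaining ties prefer 0 deg,
    then the angle closer to 0, then the more negative one.  Since 0 is
    always a candidate the chosen rotation never has a shallower valley
    than the input.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    arr = np.asarray(image, dtype=np.float64)
    threshold = iterative_threshold(arr).final_t
    n = int(round(angle_range_deg / step_deg))
    angles = [i * step_deg for i in range(-n, n + 1)]
    # evaluation order encodes the tie preference: 0, then by magnitude
    # with the negative angle first
    angles.sort(key=lambda a: (abs(a), a))

    best_angle = 0.0
    best_score: tuple[float, int] = (np.inf, 0)
    best_image = arr
    for angle in angles:
        if angle == 0.0:
            rotated = arr
        else:
            rotated = _sk_rotate(
                arr, angle, resize=False, order=1, mode="constant",
                cval=0.0, preserve_range=True,
            )
        score = _valley_score(binarize(rotated, threshold))
        if score < best_score:
            best_score = score
            best_angle = angle
            best_image = rotated
    out = np.clip(np.rint(best_image), 0, 255).astype(np.uint8)
    return out, best_angle
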