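"""8-bit grayscale image I/O (PNG/JPEG/TIFF) via Pillow."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Load an image as (H, W) uint8; color inputs go through the luma transform."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")  # ITU-R 601 luma
        return np.asarray(im, dtype=np.uint8)


def write_gray(image: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))
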