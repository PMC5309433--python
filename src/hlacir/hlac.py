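"""Direct HLAC feature extraction.

The raw feature of a mask over a region is

    F_N = sum_r I(r) * I(r + a_1) * ... * I(r + a_N)

summed over centers ``r`` inside the region.  The per-center product map
``f(r)`` is defined wherever the full 3x3 window fits inside the *image*
(for every mask, including order 0), and is zero on the one-pixel image
border; region sums count every center inside the region even when its
neighborhood extends outside the region (but inside the image).  This is
the semantics the integral-table reconstruction requires, so this module
doubles as the exact oracle for the fast path in :mod:`hlacir.integral`.

All accumulation is in int64, which is exact here: a single product is at
most 255^3 < 2^24 and image sums stay far below 2^63 for any realistic
frame size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import Mask, MaskSet
from .region import Region, check_region


@dataclass(frozen=True)
class FeatureVector:
    """HLAC descriptor of one region.

    Attributes
    ----------
    values:
        One entry per mask, in the mask set's order.  Integers for raw
        features, floats after normalization.
    normalized:
        Whether each value has been divided by the region's pixel count.
    n:
        Pixel count (w * h) of the originating region.
    """

    values: np.ndarray
    normalized: bool
    n: int

    def __len__(self) -> int:
        return len(self.values)


def _check_gray(img: np.ndarray) -> None:
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for a 3x3 mask to fit")


def autocorrelation_map(img: np.ndarray, mask: Mask) -> np.ndarray:
    """Per-center product map f(r) of one mask over the whole image.

    Returns an H x W int64 array; centers whose 3x3 window exits the image
    hold zero.
    """
    _check_gray(img)
    h, w = img.shape
    pix = img.astype(np.int64)
    inner = np.ones((h - 2, w - 2), dtype=np.int64)
    for dx, dy in mask.offsets:
        inner *= pix[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
    f = np.zeros((h, w), dtype=np.int64)
    f[1 : h - 1, 1 : w - 1] = inner
    return f


def autocorrelation_stack(img: np.ndarray, maskset: MaskSet) -> np.ndarray:
    """f-maps of every mask stacked into a (n_masks, H, W) int64 array."""
    return np.stack([autocorrelation_map(img, m) for m in maskset])


def extract_features(
    img: np.ndarray,
    maskset: MaskSet,
    region: Region | None = None,
    normalize: bool = True,
) -> FeatureVector:
    """Sum each mask's f-map over a region (default: the whole image).

    ``normalize=True`` divides every raw sum by the region's pixel count
    n = w * h, making features comparable across region sizes.
    """
    _check_gray(img)
    h, w = img.shape
    if region is None:
        region = Region(0, 0, w, h)
    check_region(region, w, h)
    stack = autocorrelation_stack(img, maskset)
    raw = stack[:, region.y : region.y + region.h, region.x : region.x + region.w].sum(
        axis=(1, 2)
    )
    if normalize:
        return FeatureVector(values=raw / region.area, normalized=True, n=region.area)
    return FeatureVector(values=raw, normalized=False, n=region.area)
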