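"""Preprocessing of endoscopy-style RGB frames.

Specular highlights (near-white reflections of the scope light on wet mucosa)
carry no chromatic information and would punch holes in the saturation
channel, so they are detected by a brightness threshold, dilated to cover
their fringes, and filled by deterministic boundary interpolation before the
image is converted to HSV saturation.  Saturation, (max-min)/max of the RGB
triple, is invariant to a common multiplicative illumination change and
emphasizes the reddish appearance of mucosa, which makes it the single
channel all feature extraction operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.restoration import inpaint_biharmonic


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the highlight-removal + color-conversion pipeline.

    Attributes
    ----------
    brightness_threshold:
        Pixels whose value channel max(R, G, B) reaches this level (8-bit
        scale) are treated as specular highlights.  Default 240.
    dilation_radius:
        The highlight mask is dilated by a square of this radius to cover
        blob fringes.  Default 2.
    """

    brightness_threshold: int = 240
    dilation_radius: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.brightness_threshold <= 255:
            raise ValueError("brightness_threshold must be in [0, 255]")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")


def _check_rgb(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 pixels")


def detect_highlights(
    img: np.ndarray, brightness_threshold: int = 240, dilation_radius: int = 2
) -> np.ndarray:
    """Binary mask of specular-highlight pixels, dilated by a square footprint.

    A pixel is marked when its value channel max(R, G, B) is at or above
    ``brightness_threshold``; the marked set is then dilated by a
    ``(2r+1) x (2r+1)`` square to cover the soft fringe around each blob.
    """
    _check_rgb(img)
    mask = img.max(axis=2) >= brightness_threshold
    if dilation_radius > 0 and mask.any():
        size = 2 * dilation_radius + 1
        mask = binary_dilation(mask, structure=np.ones((size, size), dtype=bool))
    return mask


def inpaint(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked pixels by biharmonic interpolation from the boundary.

    Pixels outside the mask are returned unchanged; masked pixels are
    replaced by the smooth (biharmonic) extension of the surrounding values.
    Deterministic for fixed inputs.
    """
    _check_rgb(img)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask dimensions must match the image")
    if not mask.any():
        return img.copy()
    if mask.all():
        raise ValueError("mask covers the entire image; nothing to interpolate from")
    filled = inpaint_biharmonic(img, mask, channel_axis=-1)
    return np.clip(np.rint(filled * 255.0), 0, 255).astype(np.uint8)


def saturation_channel(img: np.ndarray) -> np.ndarray:
    """HSV saturation as an 8-bit single-channel image.

    Per pixel ``S = round(255 * (max(R,G,B) - min(R,G,B)) / max(R,G,B))``,
    with S = 0 where the pixel is black.  S is unchanged (up to rounding)
    when all channels are scaled by a common factor, which is why this
    channel is robust to the light-dark contrast of endoscopic illumination.
    """
    _check_rgb(img)
    mx = img.max(axis=2).astype(np.float64)
    mn = img.min(axis=2).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, np.rint(255.0 * (mx - mn) / mx), 0.0)
    return s.astype(np.uint8)


def preprocess(
    img: np.ndarray,
    cfg: PreprocessConfig | None = None,
    fov_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Full pipeline: detect highlights, inpaint them, convert to saturation.

    Parameters
    ----------
    img:
        H x W x 3 uint8 RGB image.
    cfg:
        Highlight detection parameters; defaults used when omitted.
    fov_mask:
        Optional boolean H x W mask of the endoscope's circular field of
        view; pixels outside it (e.g. black corners) are zeroed in the
        output.  Default is the full frame.
    """
    cfg = cfg or PreprocessConfig()
    highlights = detect_highlights(img, cfg.brightness_threshold, cfg.dilation_radius)
    if highlights.any() and not highlights.all():
        img = inpaint(img, highlights)
    elif highlights.all():
        raise ValueError("entire frame detected as highlight; cannot preprocess")
    gray = saturation_channel(img)
    if fov_mask is not None:
        if fov_mask.shape != gray.shape:
            raise ValueError("fov_mask dimensions must match the image")
        gray = np.where(fov_mask, gray, 0).astype(np.uint8)
    return gray
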