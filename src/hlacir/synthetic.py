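"""Deterministic synthetic scenes for exercising multiscale retrieval.

Real endoscopy frames cannot be redistributed, so validation runs on
generated scenes that reproduce the properties the method actually relies
on in the *saturation* channel (the channel all features are computed
from): a smooth band-limited texture, quasi-periodic directional ridges
emulating haustral folds (each frame gets its own fold spacing and
orientation — the dominant macro-texture signature distinguishing frames),
and an embedded soft-edged elliptical lesion whose saturation contrast
against the background lies in the 20-60 range on the 8-bit scale,
straddling the default area-selection threshold of 20.  Hue is reddish and
value high, as for illuminated mucosa.

Queries are "quasi-images": an object cropped from a scene and rescaled,
emulating the same object photographed at a different shooting distance.

Everything is seeded: identical specs yield pixel-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.transform import resize

from .region import Region


@dataclass(frozen=True)
class SceneObject:
    """One embedded lesion: a raised-saturation ellipse with a soft edge.

    ``size`` is the intrinsic (w, h) bounding box; ``scale`` multiplies it
    at render time, emulating the same object seen closer or farther.
    ``shape="ellipse"`` is hard-edged; ``"blob"`` (default for generated
    databases) fades over the outer 15% of the radius, as lesions do.
    """

    x: int
    y: int
    size: tuple[int, int] = (300, 300)
    shape: str = "blob"
    sat_contrast: float = 40.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown object shape {self.shape!r}")
        if not 0.5 <= self.scale <= 2.0:
            raise ValueError("object scale must be in [0.5, 2.0]")

    def rendered_region(self) -> Region:
        w = max(1, round(self.size[0] * self.scale))
        h = max(1, round(self.size[1] * self.scale))
        return Region(self.x, self.y, w, h)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    The defaults describe an 800 x 600 frame: base saturation 100 with
    band-limited noise of amplitude 12 (Gaussian-filtered white noise,
    sigma 12 px — smooth relative to the pixel grid, like mucosal texture
    at working distance), folds of amplitude 10 and wavelength 45 px, a
    reddish hue around 0.03 and value around 0.85.
    """

    seed: int
    width: int = 800
    height: int = 600
    noise_sigma: tuple[float, float] | float = 12.0
    noise_amplitude: float = 12.0
    base_saturation: float = 100.0
    fold_amplitude: float = 10.0
    fold_wavelength: float = 45.0
    fold_angle: float = 0.6
    fold_warp: float = 0.5
    fold_warp_sigma: float = 30.0
    base_hue: float = 0.03
    hue_jitter: float = 0.01
    base_value: float = 0.85
    value_jitter: float = 0.03
    objects: tuple[SceneObject, ...] = field(default_factory=tuple)


def _band_limited(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sigma: float | tuple[float, float],
) -> np.ndarray:
    """Unit-variance smooth noise field (Gaussian-filtered white noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _object_mask(obj: SceneObject, shape: tuple[int, int]) -> np.ndarray:
    reg = obj.rendered_region()
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx = reg.x + (reg.w - 1) / 2.0
    cy = reg.y + (reg.h - 1) / 2.0
    rx, ry = reg.w / 2.0, reg.h / 2.0
    d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    if obj.shape == "ellipse":
        return (d2 <= 1.0).astype(np.float64)
    # soft-edged blob: cosine falloff over the outer 15% of the radius, so
    # the visible support nearly fills the ground-truth bounding box
    t = np.clip((np.sqrt(d2) - 0.85) / 0.15, 0.0, 1.0)
    return np.where(d2 <= 1.0, 0.5 * (1 + np.cos(np.pi * t)), 0.0)


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, list[Region]]:
    """Render a scene; returns (H x W x 3 uint8 RGB, ground-truth regions).

    The saturation field is base + band-limited noise + warped directional
    cosine folds + per-object soft masks times contrast; hue and value get
    mild band-limited jitter.  Ground truth is each object's rendered
    bounding box.  Raises when an object does not fit inside the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    sat = spec.base_saturation + spec.noise_amplitude * _band_limited(
        rng, shape, spec.noise_sigma
    )
    if spec.fold_amplitude:
        warp = spec.fold_warp * _band_limited(rng, shape, spec.fold_warp_sigma)
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        u = xx * np.cos(spec.fold_angle) + yy * np.sin(spec.fold_angle)
        sat = sat + spec.fold_amplitude * np.cos(
            2.0 * np.pi * (u / spec.fold_wavelength + warp)
        )
    hue = spec.base_hue + spec.hue_jitter * _band_limited(rng, shape, spec.noise_sigma)
    val = spec.base_value + spec.value_jitter * _band_limited(
        rng, shape, spec.noise_sigma
    )
    truth: list[Region] = []
    for obj in spec.objects:
        reg = obj.rendered_region()
        if not reg.within(spec.width, spec.height):
            raise ValueError(
                f"object region {reg.as_tuple()} exceeds {spec.width}x{spec.height} canvas"
            )
        sat = sat + obj.sat_contrast * _object_mask(obj, shape)
        truth.append(reg)
    hsv = np.stack(
        [
            np.clip(hue, 0.0, 1.0),
            np.clip(sat, 0.0, 255.0) / 255.0,
            np.clip(val, 0.0, 1.0),
        ],
        axis=-1,
    )
    rgb = np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return rgb, truth


def make_quasi_query(img: np.ndarray, region: Region, scale: float) -> np.ndarray:
    """Crop a region and rescale it, emulating a changed shooting distance.

    ``scale=1`` returns the exact crop; other scales use bilinear
    interpolation (deterministic), with a low-pass filter before
    minification as optics would apply.  Output dimensions are
    ``round(scale * region dims)``; degenerate outputs below 3x3 raise.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not region.within(img.shape[1], img.shape[0]):
        raise ValueError(f"region {region.as_tuple()} outside image bounds")
    crop = img[region.y : region.y + region.h, region.x : region.x + region.w]
    if scale == 1.0:
        return crop.copy()
    out_h = round(scale * region.h)
    out_w = round(scale * region.w)
    if out_h < 3 or out_w < 3:
        raise ValueError(f"rescaled query {out_w}x{out_h} is smaller than 3x3")
    out = resize(
        crop.astype(np.float64),
        (out_h, out_w, crop.shape[2]) if crop.ndim == 3 else (out_h, out_w),
        order=1,
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def random_scene(
    seed: int,
    canvas: tuple[int, int] = (800, 600),
    object_size: tuple[int, int] | None = None,
    sat_contrast: float | None = None,
    scale: float = 1.0,
    margin: int = 20,
) -> tuple[np.ndarray, Region]:
    """One database frame with a single randomly placed lesion.

    Emulates one frame of a heterogeneous image database: base saturation
    (70-130), noise amplitude (9-15), texture correlation length (8-16 px),
    hue, fold amplitude (6-14), spacing (25-80 px) and orientation, and the
    lesion's size (260-380 px per axis at full scale) and contrast (25-55)
    are all drawn per seed, so different seeds yield visually distinct
    frames — mild to severe inflammation differs grossly in mean saturation
    and texture — rather than re-rolls of one texture.  The default
    geometry is an 800 x 600 frame with a lesion of a few hundred pixels,
    large relative to the 10 px position stride; for a smaller ``canvas``
    all lengths (object, correlation scales, fold spacing) shrink
    proportionally.

    Returns (image, ground-truth region); all randomness derives from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    cw, ch = canvas
    geom = min(cw / 800.0, ch / 600.0)  # length scale relative to the full frame
    base_sat = float(rng.uniform(70.0, 130.0))
    noise_amp = float(rng.uniform(5.0, 9.0))
    hue = float(rng.uniform(0.01, 0.06))
    sigma = float(rng.uniform(8.0, 16.0)) * geom
    fold_amp = float(rng.uniform(10.0, 18.0))
    fold_lambda = float(rng.uniform(25.0, 80.0)) * geom
    fold_angle = float(rng.uniform(0.0, np.pi))
    if object_size is None:
        object_size = (
            max(3, round(int(rng.integers(260, 381)) * geom)),
            max(3, round(int(rng.integers(260, 381)) * geom)),
        )
    if sat_contrast is None:
        sat_contrast = float(rng.uniform(25.0, 55.0))
    ow = max(1, round(object_size[0] * scale))
    oh = max(1, round(object_size[1] * scale))
    if cw - ow - 2 * margin < 0 or ch - oh - 2 * margin < 0:
        raise ValueError("object does not fit in canvas with the given margin")
    x = int(rng.integers(margin, cw - ow - margin + 1))
    y = int(rng.integers(margin, ch - oh - margin + 1))
    obj = SceneObject(
        x=x, y=y, size=object_size, shape="blob", sat_contrast=sat_contrast, scale=scale
    )
    spec = SceneSpec(
        seed=seed,
        width=cw,
        height=ch,
        noise_sigma=sigma,
        noise_amplitude=noise_amp,
        base_saturation=base_sat,
        fold_amplitude=fold_amp,
        fold_wavelength=fold_lambda,
        fold_angle=fold_angle,
        fold_warp_sigma=30.0 * geom,
        base_hue=hue,
        objects=(obj,),
    )
    img, truth = make_scene(spec)
    return img, truth[0]
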