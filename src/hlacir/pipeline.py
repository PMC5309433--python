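"""High-level indexing and querying: glue over preprocess/hlac/integral/retrieval."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .hlac import FeatureVector, extract_features
from .integral import FeatureIndex, build_tables
from .masks import enumerate_masks
from .preprocess import preprocess
from .region import Region, check_region
from .retrieval import RetrievalResult, retrieve


def build_index(
    images: dict[str, np.ndarray], run_cfg: RunConfig | None = None
) -> FeatureIndex:
    """Preprocess RGB images and build integral feature tables for each.

    ``images`` maps image id to an H x W x 3 uint8 RGB array.
    """
    run_cfg = run_cfg or RunConfig()
    maskset = enumerate_masks(2, run_cfg.mask_variant)
    index = FeatureIndex(
        mask_variant=run_cfg.mask_variant,
        config_hash=run_cfg.feature_config_hash(),
        config=run_cfg.to_dict(),
    )
    for image_id in sorted(images):
        gray = preprocess(images[image_id], run_cfg.preprocess)
        index.add(build_tables(gray, maskset, image_id=image_id))
    return index


def valid_center_inset(region: Region, width: int, height: int) -> Region:
    """Shrink a region by 1 px on each edge that lies on the image boundary.

    Centers on the one-pixel image border have no complete 3x3 neighborhood
    and contribute zero to every feature; counting them while normalizing by
    w x h would bias the query's features low.  Insetting the region where
    (and only where) it touches the boundary makes every counted center
    valid while leaving interior regions untouched.
    """
    x, y, w, h = region.as_tuple()
    if x == 0:
        x, w = 1, w - 1
    if y == 0:
        y, h = 1, h - 1
    if x + w == width:
        w -= 1
    if y + h == height:
        h -= 1
    if w < 1 or h < 1:
        raise ValueError("region too small to inset away from the image boundary")
    return Region(x, y, w, h)


def query_features_from_image(
    query_rgb: np.ndarray,
    region: Region | None = None,
    run_cfg: RunConfig | None = None,
) -> tuple[FeatureVector, Region]:
    """Preprocess a query image and extract its normalized descriptor.

    ``region=None`` uses the whole frame.  The effective region (after the
    boundary inset of :func:`valid_center_inset`) is returned alongside the
    features; its size defines the candidate grid.
    """
    run_cfg = run_cfg or RunConfig()
    maskset = enumerate_masks(2, run_cfg.mask_variant)
    gray = preprocess(query_rgb, run_cfg.preprocess)
    h, w = gray.shape
    if region is None:
        region = Region(0, 0, w, h)
    check_region(region, w, h)
    region = valid_center_inset(region, w, h)
    feats = extract_features(gray, maskset, region, normalize=True)
    return feats, region


def query_index(
    index: FeatureIndex,
    query_rgb: np.ndarray,
    region: Region | None = None,
    run_cfg: RunConfig | None = None,
) -> RetrievalResult:
    """End-to-end query: preprocess, extract, enumerate, select, rank."""
    run_cfg = run_cfg or RunConfig()
    if index.mask_variant and index.mask_variant != run_cfg.mask_variant:
        raise ValueError(
            f"index mask variant {index.mask_variant!r} does not match "
            f"query configuration {run_cfg.mask_variant!r}"
        )
    feats, eff_region = query_features_from_image(query_rgb, region, run_cfg)
    return retrieve(index, feats, (eff_region.w, eff_region.h), run_cfg.retrieval)
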