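"""Integral feature tables: O(1) HLAC features for any rectangle.

For each mask, the cumulative table

    G(x, y) = sum_{x' < x, y' < y} f(x', y')

is stored with a zero guard row and column, so the raw feature of the
half-open region [x, x+w) x [y, y+h) is reconstructed from four corner
reads:

    F = G(x+w, y+h) - G(x+w, y) - G(x, y+h) + G(x, y)

independent of the region's area.  Tables hold exact int64 values, so the
reconstruction agrees with direct summation to strict integer equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .hlac import FeatureVector, autocorrelation_stack
from .masks import MaskSet
from .region import Region, check_region

_FORMAT_VERSION = 1


class IndexFormatError(Exception):
    """Raised when an index file is corrupt or incompatible."""


@dataclass
class ImageEntry:
    """Integral feature tables of one indexed image.

    ``tables`` has shape (n_masks, H+1, W+1); ``tables[k, y, x]`` is the sum
    of mask k's f-map over the half-open box [0, x) x [0, y).
    """

    image_id: str
    tables: np.ndarray
    width: int
    height: int
    table_reads: int = 0  # cumulative corner-read count, for cost accounting

    @property
    def n_masks(self) -> int:
        return self.tables.shape[0]


@dataclass
class FeatureIndex:
    """A database of :class:`ImageEntry` under one feature configuration."""

    mask_variant: str
    config_hash: str = ""
    config: dict = field(default_factory=dict)
    images: dict[str, ImageEntry] = field(default_factory=dict)

    def add(self, entry: ImageEntry) -> None:
        self.images[entry.image_id] = entry

    def __len__(self) -> int:
        return len(self.images)


def build_tables(img: np.ndarray, maskset: MaskSet, image_id: str = "") -> ImageEntry:
    """Build one integral table per mask from a preprocessed gray image."""
    stack = autocorrelation_stack(img, maskset)  # validates size
    k, h, w = stack.shape
    tables = np.zeros((k, h + 1, w + 1), dtype=np.int64)
    np.cumsum(stack, axis=1, out=stack)
    np.cumsum(stack, axis=2, out=stack)
    tables[:, 1:, 1:] = stack
    return ImageEntry(image_id=image_id, tables=tables, width=w, height=h)


def rect_sums(
    tables: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
) -> np.ndarray:
    """Vectorized four-corner sums: (n_masks, n_regions) raw features."""
    return (
        tables[:, y + h, x + w]
        - tables[:, y, x + w]
        - tables[:, y + h, x]
        + tables[:, y, x]
    )


def region_features(
    entry: ImageEntry, region: Region, normalize: bool = True
) -> FeatureVector:
    """HLAC features of a region from four table reads per mask.

    The number of table accesses is 4 x n_masks regardless of the region's
    size; ``entry.table_reads`` is incremented accordingly so the constant
    cost is observable.
    """
    check_region(region, entry.width, entry.height)
    x, y, w, h = region.as_tuple()
    g = entry.tables
    raw = g[:, y + h, x + w] - g[:, y, x + w] - g[:, y + h, x] + g[:, y, x]
    entry.table_reads += 4 * entry.n_masks
    if normalize:
        return FeatureVector(values=raw / region.area, normalized=True, n=region.area)
    return FeatureVector(values=raw, normalized=False, n=region.area)


def save_index(index: FeatureIndex, path: str) -> None:
    """Write an index to HDF5: /images/<id>/mask_<k> datasets + /meta JSON."""
    with h5py.File(path, "w") as f:
        meta = {
            "format_version": _FORMAT_VERSION,
            "mask_variant": index.mask_variant,
            "config_hash": index.config_hash,
            "config": index.config,
            "image_ids": sorted(index.images),
        }
        f.attrs["meta"] = json.dumps(meta)
        grp = f.create_group("images")
        for image_id, entry in sorted(index.images.items()):
            g = grp.create_group(image_id)
            g.attrs["width"] = entry.width
            g.attrs["height"] = entry.height
            for k in range(entry.n_masks):
                g.create_dataset(f"mask_{k}", data=entry.tables[k], compression="gzip")


def load_index(path: str, expected_config_hash: str | None = None) -> FeatureIndex:
    """Read an index from HDF5, validating layout and (optionally) the hash.

    Parameters
    ----------
    expected_config_hash:
        When given (strict mode), loading fails with
        :class:`IndexFormatError` unless the stored feature-configuration
        hash matches.
    """
    try:
        with h5py.File(path, "r") as f:
            try:
                meta = json.loads(f.attrs["meta"])
            except (KeyError, json.JSONDecodeError) as e:
                raise IndexFormatError(f"missing or corrupt index metadata: {e}")
            if meta.get("format_version") != _FORMAT_VERSION:
                raise IndexFormatError(
                    f"unsupported index format version {meta.get('format_version')!r}"
                )
            if (
                expected_config_hash is not None
                and meta.get("config_hash") != expected_config_hash
            ):
                raise IndexFormatError(
                    "index was built under a different feature configuration "
                    f"(hash {meta.get('config_hash')!r} != expected {expected_config_hash!r})"
                )
            index = FeatureIndex(
                mask_variant=meta.get("mask_variant", ""),
                config_hash=meta.get("config_hash", ""),
                config=meta.get("config", {}),
            )
            grp = f.get("images")
            if grp is None:
                raise IndexFormatError("index file has no /images group")
            for image_id in grp:
                g = grp[image_id]
                keys = sorted(g, key=lambda s: int(s.split("_")[1]))
                tables = np.stack([g[k][()] for k in keys]).astype(np.int64)
                width = int(g.attrs["width"])
                height = int(g.attrs["height"])
                if tables.shape[1:] != (height + 1, width + 1):
                    raise IndexFormatError(
                        f"table dimensions inconsistent for image {image_id!r}"
                    )
                index.add(
                    ImageEntry(
                        image_id=image_id, tables=tables, width=width, height=height
                    )
                )
            return index
    except OSError as e:
        raise IndexFormatError(f"cannot read index file {path!r}: {e}")
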