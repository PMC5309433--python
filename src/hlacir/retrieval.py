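"""Multiscale candidate enumeration and coarse-to-fine region retrieval.

A query of size (qw, qh) is searched for in every indexed image by
enumerating rectangular candidates whose sizes span +/- ``scale_range_pct``
percent of the query size and whose positions lie on a stride grid.  The
candidate set is then thinned in the order a human searcher would:

1. *Area selection* — per image, keep candidates whose mean intensity
   (normalized 0th-order feature, four table reads) is close to the
   query's, both in absolute value and in rank.
2. *Image selection* — drop whole images stepwise: first those whose best
   candidate is too far in the 0th-order feature, then in the four
   1st-order features; the survivors are ranked by the full Euclidean
   distance over all mask components.

Smaller distance means more similar; a "threshold of 5" keeps images whose
best candidate is at distance < 5.  Thresholds operate on normalized
features (per-pixel ratios), so they are comparable across region sizes
and expressed on the 8-bit intensity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hlac import FeatureVector
from .integral import FeatureIndex, ImageEntry, rect_sums
from .masks import CENTER_NO_REPEAT, enumerate_masks
from .region import Region


@dataclass(frozen=True)
class RetrievalConfig:
    """Candidate-grid and selection thresholds.

    Defaults are the standard operating point of the method: sizes within
    +/-10% of the query stepped by 1 px on the reference axis, positions
    every 10 px, area selection keeping candidates with mean-intensity
    difference < 20 that also rank in the best 10%, and image-selection
    thresholds of 5 (0th order) and 50 (1st order).
    """

    scale_range_pct: float = 10.0
    position_stride_px: int = 10
    size_step_px: int = 1
    area_sim_threshold: float = 20.0
    area_rank_fraction: float = 0.10
    stage0_threshold: float = 5.0
    stage1_threshold: float = 50.0
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.position_stride_px < 1 or self.size_step_px < 1:
            raise ValueError("strides must be >= 1")
        if not 0 < self.area_rank_fraction <= 1:
            raise ValueError("area_rank_fraction must be in (0, 1]")
        for name in ("area_sim_threshold", "stage0_threshold", "stage1_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scale_range_pct < 0:
            raise ValueError("scale_range_pct must be >= 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class RankedMatch:
    image_id: str
    region: Region
    distance: float


@dataclass
class RetrievalResult:
    """Ranked matches plus per-stage survivor counts (images, candidates)."""

    ranking: list[RankedMatch]
    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)

    def counts_as_rows(self) -> list[dict]:
        return [
            {"stage": s, "images": i, "candidates": c}
            for s, i, c in self.stage_counts
        ]


def similarity(
    u: FeatureVector, v: FeatureVector, components: np.ndarray | None = None
) -> float:
    """Euclidean distance between two normalized feature vectors.

    ``components`` restricts the comparison to a sub-vector (e.g. only the
    0th-order component, or only the four 1st-order components).
    """
    if len(u) != len(v):
        raise ValueError(f"feature length mismatch: {len(u)} vs {len(v)}")
    if not (u.normalized and v.normalized):
        raise ValueError("similarity is defined on normalized feature vectors")
    a, b = u.values, v.values
    if components is not None:
        a, b = a[components], b[components]
    return float(np.linalg.norm(a - b))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def candidate_sizes(
    query_w: int, query_h: int, cfg: RetrievalConfig
) -> list[tuple[int, int]]:
    """Sizes (w, h) spanning +/- scale_range_pct of the query size.

    A single scale-factor grid is applied to both axes (aspect ratio
    preserved); the grid is defined by ``size_step_px`` steps on the longer
    axis, and the shorter axis follows by rounding.
    """
    if query_w < 1 or query_h < 1:
        raise ValueError("query size must be positive")
    frac = cfg.scale_range_pct / 100.0
    ref, other = (query_w, query_h) if query_w >= query_h else (query_h, query_w)
    lo = max(1, _round_half_up((1.0 - frac) * ref))
    hi = _round_half_up((1.0 + frac) * ref)
    sizes: list[tuple[int, int]] = []
    for s in range(lo, hi + 1, cfg.size_step_px):
        o = max(1, _round_half_up(s / ref * other))
        sizes.append((s, o) if query_w >= query_h else (o, s))
    return sizes


def count_candidates(
    target_w: int, target_h: int, query_w: int, query_h: int, cfg: RetrievalConfig
) -> int:
    """Closed-form candidate count: sum over sizes of the position-grid size."""
    stride = cfg.position_stride_px
    total = 0
    for w, h in candidate_sizes(query_w, query_h, cfg):
        if w <= target_w and h <= target_h:
            total += ((target_w - w) // stride + 1) * ((target_h - h) // stride + 1)
    return total


def enumerate_candidates(
    target_w: int, target_h: int, query_w: int, query_h: int, cfg: RetrievalConfig
) -> np.ndarray:
    """All candidate regions as an (n, 4) int64 array of (x, y, w, h).

    Sizes come from :func:`candidate_sizes`; positions lie on the
    ``position_stride_px`` grid anchored at the origin, with every region
    fully inside the target.  Empty when no size fits.
    """
    stride = cfg.position_stride_px
    blocks: list[np.ndarray] = []
    for w, h in candidate_sizes(query_w, query_h, cfg):
        if w > target_w or h > target_h:
            continue
        xs = np.arange(0, target_w - w + 1, stride, dtype=np.int64)
        ys = np.arange(0, target_h - h + 1, stride, dtype=np.int64)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        n = gx.size
        block = np.empty((n, 4), dtype=np.int64)
        block[:, 0] = gx.ravel()
        block[:, 1] = gy.ravel()
        block[:, 2] = w
        block[:, 3] = h
        blocks.append(block)
    if not blocks:
        return np.empty((0, 4), dtype=np.int64)
    return np.concatenate(blocks)


def _normalized_components(
    entry: ImageEntry, cands: np.ndarray, components: np.ndarray
) -> np.ndarray:
    """Normalized feature components of many candidates, (n_comp, n_cand)."""
    x, y, w, h = cands[:, 0], cands[:, 1], cands[:, 2], cands[:, 3]
    raw = rect_sums(entry.tables[components], x, y, w, h)
    entry.table_reads += 4 * len(components) * len(cands)
    return raw / (w * h)


def area_select(
    entry: ImageEntry,
    query_f0: float,
    candidates: np.ndarray,
    cfg: RetrievalConfig,
) -> np.ndarray:
    """First-stage filter on mean intensity, via the 0th-order table only.

    A candidate survives when its |mean - query mean| is strictly below
    ``area_sim_threshold`` AND within the best ``area_rank_fraction`` of
    this image's candidates (ties at the rank cutoff all kept).
    """
    if len(candidates) == 0:
        return candidates
    vals = np.abs(
        _normalized_components(entry, candidates, np.array([0]))[0] - query_f0
    )
    n = len(vals)
    k = min(n, max(1, math.ceil(cfg.area_rank_fraction * n)))
    cutoff = np.partition(vals, k - 1)[k - 1]
    keep = (vals < cfg.area_sim_threshold) & (vals <= cutoff)
    return candidates[keep]


def stage_components(variant: str = CENTER_NO_REPEAT) -> tuple[np.ndarray, np.ndarray]:
    """Feature indices of the order-0 and order-1 masks for a variant."""
    orders = np.array([m.order for m in enumerate_masks(2, variant)])
    return np.flatnonzero(orders == 0), np.flatnonzero(orders == 1)


def _best_candidate(
    cands: np.ndarray, dist: np.ndarray
) -> tuple[int, float]:
    """Index + distance of the best candidate; ties broken by (y, x, w, h)."""
    order = np.lexsort(
        (cands[:, 3], cands[:, 2], cands[:, 0], cands[:, 1], dist)
    )
    i = int(order[0])
    return i, float(dist[i])


def image_select(
    index: FeatureIndex,
    query_features: FeatureVector,
    survivors: dict[str, np.ndarray],
    cfg: RetrievalConfig,
) -> RetrievalResult:
    """Stepwise image elimination and final full-vector ranking.

    Stage 0 drops images whose best candidate's 0th-order distance is not
    below ``stage0_threshold``; stage 1 repeats with the four 1st-order
    components and ``stage1_threshold``; surviving images are ranked by
    their best candidate under the full Euclidean distance, ties broken by
    (image id, y, x, w, h).
    """
    comp0, comp1 = stage_components(index.mask_variant or CENTER_NO_REPEAT)
    qv = query_features.values
    counts: list[tuple[str, int, int]] = []
    alive = {iid: c for iid, c in survivors.items() if len(c) > 0}
    counts.append(
        ("area_selection", len(alive), sum(len(c) for c in alive.values()))
    )

    for stage_name, comps, threshold in (
        ("image_selection_order0", comp0, cfg.stage0_threshold),
        ("image_selection_order1", comp1, cfg.stage1_threshold),
    ):
        nxt: dict[str, np.ndarray] = {}
        for iid, cands in alive.items():
            feats = _normalized_components(index.images[iid], cands, comps)
            dist = np.sqrt(((feats - qv[comps, None]) ** 2).sum(axis=0))
            if dist.min() < threshold:
                nxt[iid] = cands
        alive = nxt
        counts.append(
            (stage_name, len(alive), sum(len(c) for c in alive.values()))
        )

    all_comps = np.arange(len(qv))
    ranked: list[RankedMatch] = []
    for iid in sorted(alive):
        cands = alive[iid]
        feats = _normalized_components(index.images[iid], cands, all_comps)
        dist = np.sqrt(((feats - qv[:, None]) ** 2).sum(axis=0))
        i, d = _best_candidate(cands, dist)
        x, y, w, h = (int(v) for v in cands[i])
        ranked.append(RankedMatch(iid, Region(x, y, w, h), d))
    ranked.sort(key=lambda m: (m.distance, m.image_id))
    return RetrievalResult(ranking=ranked[: cfg.top_k], stage_counts=counts)


def retrieve(
    index: FeatureIndex,
    query_features: FeatureVector,
    query_size: tuple[int, int],
    cfg: RetrievalConfig | None = None,
) -> RetrievalResult:
    """Full pipeline: enumerate, area-select per image, then image-select.

    Parameters
    ----------
    query_features:
        Normalized HLAC descriptor of the query region.
    query_size:
        (width, height) of the query region, defining the candidate size
        grid.
    """
    cfg = cfg or RetrievalConfig()
    qw, qh = query_size
    qf0 = float(query_features.values[stage_components(index.mask_variant or CENTER_NO_REPEAT)[0][0]])
    survivors: dict[str, np.ndarray] = {}
    n_initial = 0
    n_images_initial = 0
    for iid in sorted(index.images):
        entry = index.images[iid]
        cands = enumerate_candidates(entry.width, entry.height, qw, qh, cfg)
        if len(cands):
            n_images_initial += 1
        n_initial += len(cands)
        survivors[iid] = area_select(entry, qf0, cands, cfg)
    result = image_select(index, query_features, survivors, cfg)
    result.stage_counts.insert(0, ("initial", n_images_initial, n_initial))
    return result
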