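"""Enumeration of higher-order local autocorrelation (HLAC) masks.

An HLAC mask is a multiset of pixel offsets within a 3x3 window, always
containing the window center ``(0, 0)``.  Each mask defines one product term
:math:`I(r) \\cdot I(r+a_1) \\cdots I(r+a_N)` of the autocorrelation of order
*N* (the number of displacement vectors, at most 2 here).  Two masks that are
whole-pattern translations of one another inside the 3x3 window describe the
same shift-invariant statistic and are identified; the enumeration below
yields the classical 35 translation-inequivalent gray-scale masks for
:math:`N \\le 2`, and the reduced 25-mask set in which no pixel (center
included) is multiplied with itself — i.e. no squares or cubes appear in the
product.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterator

Offset = tuple[int, int]

#: Valid set-variant names.
FULL_GRAYSCALE = "full_grayscale"
CENTER_NO_REPEAT = "center_no_repeat"

_WINDOW: tuple[Offset, ...] = tuple(
    (dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
)


def _in_window(off: Offset) -> bool:
    return -1 <= off[0] <= 1 and -1 <= off[1] <= 1


def canonicalize(offsets: tuple[Offset, ...]) -> tuple[Offset, ...]:
    """Return the canonical representative of a mask's translation class.

    Among all translations of the offset multiset that keep every offset in
    the 3x3 window and keep ``(0, 0)`` in the multiset, the lexicographically
    smallest sorted tuple is chosen.  Candidate translations are exactly those
    that move one of the existing offsets onto the center.

    Parameters
    ----------
    offsets:
        Multiset of ``(dx, dy)`` pairs, each in {-1, 0, 1}^2, containing
        ``(0, 0)``.
    """
    if (0, 0) not in offsets:
        raise ValueError("mask must contain the center offset (0, 0)")
    best: tuple[Offset, ...] | None = None
    for ox, oy in set(offsets):
        shifted = tuple(sorted((dx - ox, dy - oy) for dx, dy in offsets))
        if all(_in_window(o) for o in shifted):
            if best is None or shifted < best:
                best = shifted
    assert best is not None  # identity translation always qualifies
    return best


@dataclass(frozen=True)
class Mask:
    """One HLAC product pattern in canonical form.

    Attributes
    ----------
    offsets:
        Sorted tuple of ``(dx, dy)`` offsets with multiplicity (length =
        order + 1); the canonical representative of the translation class.
    index:
        1-based position of the mask within its :class:`MaskSet`, stable
        across runs (masks are ordered by ascending order, then
        lexicographically by canonical offsets).
    """

    offsets: tuple[Offset, ...]
    index: int = 0

    @property
    def order(self) -> int:
        """Autocorrelation order N = number of displacements."""
        return len(self.offsets) - 1

    @property
    def max_multiplicity(self) -> int:
        return max(Counter(self.offsets).values())

    def to_dict(self) -> dict:
        counts = Counter(self.offsets)
        return {
            "index": self.index,
            "order": self.order,
            "offsets": [
                {"dx": dx, "dy": dy, "multiplicity": m}
                for (dx, dy), m in sorted(counts.items())
            ],
        }


@dataclass(frozen=True)
class MaskSet:
    """Ordered, deduplicated collection of masks of one variant."""

    masks: tuple[Mask, ...]
    variant: str
    max_order: int = 2

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[Mask]:
        return iter(self.masks)

    def __getitem__(self, i: int) -> Mask:
        return self.masks[i]

    def order_histogram(self) -> dict[int, int]:
        hist: Counter[int] = Counter(m.order for m in self.masks)
        return dict(sorted(hist.items()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "max_order": self.max_order,
                "masks": [m.to_dict() for m in self.masks],
            },
            indent=2,
        )


def _enumerate_canonical(max_order: int) -> list[tuple[Offset, ...]]:
    seen: set[tuple[Offset, ...]] = set()
    for k in range(1, max_order + 2):
        for combo in combinations_with_replacement(_WINDOW, k):
            if (0, 0) not in combo:
                continue
            seen.add(canonicalize(combo))
    return sorted(seen, key=lambda c: (len(c), c))


def enumerate_masks(max_order: int = 2, variant: str = CENTER_NO_REPEAT) -> MaskSet:
    """Enumerate all translation-inequivalent HLAC masks up to ``max_order``.

    Parameters
    ----------
    max_order:
        Highest autocorrelation order N, one of {0, 1, 2}.
    variant:
        ``"full_grayscale"`` keeps every pattern (35 masks at order 2);
        ``"center_no_repeat"`` drops patterns in which any single pixel
        appears with multiplicity >= 2, so every mask is a product of
        distinct pixels (25 masks at order 2).

    Returns
    -------
    MaskSet
        Masks ordered by ascending order N, then lexicographic canonical
        form, with 1-based ``index`` assigned in that order.
    """
    if max_order not in (0, 1, 2):
        raise ValueError(f"max_order must be in {{0, 1, 2}}, got {max_order!r}")
    if variant not in (FULL_GRAYSCALE, CENTER_NO_REPEAT):
        raise ValueError(f"unknown variant {variant!r}")
    canon = _enumerate_canonical(max_order)
    if variant == CENTER_NO_REPEAT:
        canon = [c for c in canon if max(Counter(c).values()) == 1]
    masks = tuple(Mask(offsets=c, index=i + 1) for i, c in enumerate(canon))
    return MaskSet(masks=masks, variant=variant, max_order=max_order)


def excluded_masks(max_order: int = 2) -> MaskSet:
    """The masks present in the full gray-scale set but not in the reduced set.

    Every returned mask multiplies some pixel with itself (a square or cube
    term).  At ``max_order=2`` there are exactly 10 such masks.
    """
    if max_order != 2:
        raise ValueError("excluded_masks is defined for max_order=2")
    full = {m.offsets for m in enumerate_masks(max_order, FULL_GRAYSCALE)}
    reduced = {m.offsets for m in enumerate_masks(max_order, CENTER_NO_REPEAT)}
    canon = sorted(full - reduced, key=lambda c: (len(c), c))
    masks = tuple(Mask(offsets=c, index=i + 1) for i, c in enumerate(canon))
    return MaskSet(masks=masks, variant="excluded", max_order=max_order)
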