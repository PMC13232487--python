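"""Crown-like structure (CLS) detection.

A crown-like structure is a ring of F4/80-positive macrophages surrounding
a dead or dying adipocyte — the histological hallmark of adipose tissue
inflammation.  On an F4/80 IHC section the macrophages appear reddish-brown
against a bluish counterstain, so a pixel is called stained when its raw
red-to-blue channel ratio strictly exceeds a threshold (default 1.05).

Per cell, the "area surrounding the membrane" is realized as a symmetric
morphological annulus: the cell mask dilated by ``ring_width`` minus the
mask eroded by ``ring_width`` (isotropic disk element, default width 3 px).
The decision statistic is the stained fraction of that annulus; a cell is a
CLS when the fraction strictly exceeds ``membrane_fraction_threshold``
(default 0.30, i.e. more than 30% of the membrane area stained).

Both inequalities are strict: a ratio of exactly 1.05 is not stained and a
fraction of exactly 0.30 is not a CLS.  Cells sharing ring pixels are
scored independently — stain lying between two adjacent cells counts
toward both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .segmentation import CellRecord, SegmentationResult

__all__ = [
    "ClsParams",
    "ClsScore",
    "stain_mask",
    "membrane_ring",
    "score_cell",
    "score_field",
    "field_cls_percentage",
]


@dataclass(frozen=True)
class ClsParams:
    """Thresholds and geometry of the CLS classifier.

    Attributes
    ----------
    rb_ratio_threshold:
        A pixel is F4/80-stained iff red/blue strictly exceeds this
        (dimensionless, default 1.05).
    membrane_fraction_threshold:
        A cell is a CLS iff its stained membrane fraction strictly exceeds
        this (default 0.30).
    ring_width:
        Half-width in pixels of the morphological membrane annulus
        (default 3).
    """

    rb_ratio_threshold: float = 1.05
    membrane_fraction_threshold: float = 0.30
    ring_width: int = 3

    def __post_init__(self) -> None:
        if not self.rb_ratio_threshold > 0:
            raise ValueError("rb_ratio_threshold must be > 0")
        if not 0 < self.membrane_fraction_threshold < 1:
            raise ValueError("membrane_fraction_threshold must be in (0, 1)")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")


@dataclass
class ClsScore:
    """Per-cell stained-membrane coverage and CLS call."""

    label: int
    ring_px: int
    stained_ring_px: int
    stained_fraction: float
    is_cls: bool


def stain_mask(rgb: np.ndarray, rb_ratio_threshold: float = 1.05) -> np.ndarray:
    """Per-pixel F4/80 stain call on raw 8-bit channels.

    A pixel is stained iff ``R / B > rb_ratio_threshold`` (strict), computed
    on the original channel values with no white-balance correction.  The
    comparison is done multiplicatively (``R > threshold * B``) so the
    degenerate blue=0 cases are well defined: (R>0, B=0) is stained,
    (R=0, B=0) is not.
    """
    if not rb_ratio_threshold > 0:
        raise ValueError("rb_ratio_threshold must be > 0")
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {rgb.shape}")
    r = rgb[..., 0].astype(np.float64)
    b = rgb[..., 2].astype(np.float64)
    return r > rb_ratio_threshold * b


def membrane_ring(
    label_map: np.ndarray, cell_label: int, ring_width: int = 3
) -> np.ndarray:
    """Morphological annulus around one cell's boundary.

    ``dilation(mask, disk(w)) & ~erosion(mask, disk(w))`` — a band of
    roughly ``2 * ring_width`` pixels straddling the cell edge, clipped to
    the image bounds.  Pixels inside a neighboring cell are retained: stain
    between cells is part of both membranes' surroundings.
    """
    label_map = np.asarray(label_map)
    if cell_label <= 0 or not (label_map == cell_label).any():
        raise KeyError(f"label {cell_label} not present in label map")
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")

    # Work on a bbox crop padded by ring_width for speed; dilation cannot
    # reach further than the pad, so the crop is exact.
    rows, cols = np.nonzero(label_map == cell_label)
    h, w = label_map.shape
    r0 = max(rows.min() - ring_width, 0)
    r1 = min(rows.max() + ring_width + 1, h)
    c0 = max(cols.min() - ring_width, 0)
    c1 = min(cols.max() + ring_width + 1, w)
    crop = label_map[r0:r1, c0:c1] == cell_label

    selem = disk(ring_width)
    dilated = ndimage.binary_dilation(crop, structure=selem)
    eroded = ndimage.binary_erosion(crop, structure=selem)
    ring_crop = dilated & ~eroded

    ring = np.zeros((h, w), dtype=bool)
    ring[r0:r1, c0:c1] = ring_crop
    return ring


def score_cell(
    ring: np.ndarray,
    stain: np.ndarray,
    membrane_fraction_threshold: float = 0.30,
    label: int = 0,
) -> ClsScore:
    """Score one cell: stained fraction of its membrane ring and CLS call.

    ``stained_fraction = |ring & stain| / |ring|``; the cell is a CLS iff
    the fraction strictly exceeds the threshold.
    """
    ring = np.asarray(ring, dtype=bool)
    stain = np.asarray(stain, dtype=bool)
    ring_px = int(ring.sum())
    if ring_px == 0:
        raise ValueError(f"empty membrane ring for cell label {label}")
    stained_px = int((ring & stain).sum())
    fraction = stained_px / ring_px
    return ClsScore(
        label=label,
        ring_px=ring_px,
        stained_ring_px=stained_px,
        stained_fraction=fraction,
        is_cls=fraction > membrane_fraction_threshold,
    )


def score_field(
    rgb: np.ndarray,
    segmentation: SegmentationResult,
    params: ClsParams | None = None,
) -> list[ClsScore]:
    """Score every segmented cell of a field against the F4/80 stain mask."""
    params = params or ClsParams()
    stain = stain_mask(rgb, params.rb_ratio_threshold)
    scores = []
    for cell in segmentation.cells:
        ring = membrane_ring(
            segmentation.label_map, cell.label, params.ring_width
        )
        scores.append(
            score_cell(
                ring,
                stain,
                params.membrane_fraction_threshold,
                label=cell.label,
            )
        )
    return scores


def field_cls_percentage(
    scores: Sequence[ClsScore], cells: Sequence[CellRecord]
) -> float:
    """Percentage of filter-passing cells classified as CLS, in [0, 100].

    Only cells with ``passed_filters`` enter the denominator, so the CLS
    population matches the morphometry population.  A field with zero
    passing cells has no defined percentage and raises instead of
    reporting 0.
    """
    passed = {c.label for c in cells if c.passed_filters}
    if not passed:
        raise ValueError("no filter-passing cells in field; %CLS is undefined")
    by_label = {s.label: s for s in scores}
    missing = passed - by_label.keys()
    if missing:
        raise ValueError(f"missing CLS scores for cell labels {sorted(missing)}")
    n_cls = sum(1 for lbl in passed if by_label[lbl].is_cls)
    return 100.0 * n_cls / len(passed)
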