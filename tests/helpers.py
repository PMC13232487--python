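"""Independent brute-force oracles and matching utilities for the tests.

These deliberately avoid the library code paths they check: flood fill is
a hand-written stack walk, morphology is explicit set arithmetic over
pixel offsets, and the ANOVA reference is a permutation test.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    next_label = 0
    for sr in range(h):
        for sc in range(w):
            if not mask[sr, sc] or labels[sr, sc]:
                continue
            next_label += 1
            stack = [(sr, sc)]
            labels[sr, sc] = next_label
            while stack:
                r, c = stack.pop()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = next_label
                        stack.append((rr, cc))
    return labels


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Integer offsets within Euclidean distance `radius` of the origin."""
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                out.append((dr, dc))
    return out


def brute_force_ring(mask: np.ndarray, width: int) -> np.ndarray:
    """Annulus by explicit set arithmetic: dilate(mask) & ~erode(mask).

    Dilation = pixels within distance `width` of some mask pixel; erosion =
    pixels whose whole distance-`width` disk (clipped shifts included per
    the standard definition) lies inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    offs = disk_offsets(width)
    dilated = np.zeros_like(mask)
    eroded = np.ones_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            allin = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                inside = 0 <= rr < h and 0 <= cc < w
                if inside and mask[rr, cc]:
                    hit = True
                if inside and not mask[rr, cc]:
                    allin = False
            dilated[r, c] = hit
            eroded[r, c] = allin and mask[r, c]
    return dilated & ~eroded


def permutation_anova_p(
    samples: list[np.ndarray], n_shuffles: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for the one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in samples]
    pooled = np.concatenate(samples)
    f_obs = f_oneway(*samples).statistic
    count = 0
    for _ in range(n_shuffles):
        rng.shuffle(pooled)
        parts = np.split(pooled, np.cumsum(sizes)[:-1])
        if f_oneway(*parts).statistic >= f_obs:
            count += 1
    return (count + 1) / (n_shuffles + 1)


def match_truth_to_segmentation(truth, seg) -> dict[int, int]:
    """Map each planted cell label to the segmented label covering it.

    Uses majority overlap of the planted lumen raster with the recovered
    label map; a planted cell mapped to background (0) means a miss.
    """
    mapping = {}
    for cell in truth.cells:
        m = truth.label_raster == cell.label
        overlap = seg.label_map[m]
        mapping[cell.label] = int(np.bincount(overlap).argmax())
    return mapping


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
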