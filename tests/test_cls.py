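"""CLS detection: stain ratio calling, membrane rings, the >30% rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipoquant import (
    ClsParams,
    field_cls_percentage,
    generate_field,
    membrane_ring,
    score_cell,
    score_field,
    segment_field,
    stain_mask,
)
from adipoquant.segmentation import CellRecord
from conftest import noise_free
from helpers import brute_force_ring, match_truth_to_segmentation


def _pixel(r, g, b):
    return np.array([[[r, g, b]]], dtype=np.uint8)


class TestStainMask:
    @pytest.mark.parametrize(
        "r, b, stained",
        [
            (106, 100, True),  # ratio 1.06: exceeds 1.05
            (105, 100, False),  # ratio exactly 1.05: not exceeded
            (0, 0, False),  # black: defined unstained
            (1, 0, True),  # red with zero blue: stained
            (0, 100, False),
        ],
    )
    def test_ratio_boundary(self, r, b, stained):
        assert bool(stain_mask(_pixel(r, 50, b))[0, 0]) is stained

    def test_green_channel_ignored(self, rng):
        rgb = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        alt = rgb.copy()
        alt[..., 1] = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        np.testing.assert_array_equal(stain_mask(rgb), stain_mask(alt))

    @given(st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold(self, r, b):
        """Raising the ratio threshold can only unstain pixels."""
        px = _pixel(r, 0, b)
        low = stain_mask(px, 1.05)[0, 0]
        high = stain_mask(px, 1.50)[0, 0]
        assert not (high and not low)


class TestMembraneRing:
    def test_single_pixel_cell_matches_set_arithmetic(self):
        label_map = np.zeros((5, 5), dtype=int)
        label_map[2, 2] = 1
        ring = membrane_ring(label_map, 1, ring_width=1)
        oracle = brute_force_ring(label_map == 1, width=1)
        np.testing.assert_array_equal(ring, oracle)

    def test_disk_annulus_matches_brute_force(self):
        rows, cols = np.mgrid[0:40, 0:40]
        label_map = (np.hypot(rows - 20, cols - 20) <= 10).astype(int)
        ring = membrane_ring(label_map, 1, ring_width=3)
        oracle = brute_force_ring(label_map == 1, width=3)
        np.testing.assert_array_equal(ring, oracle)
        assert ring.sum() == oracle.sum() > 0

    def test_border_cell_ring_clipped_but_nonempty(self):
        label_map = np.zeros((20, 20), dtype=int)
        label_map[0:5, 0:5] = 1
        ring = membrane_ring(label_map, 1, ring_width=3)
        assert ring.sum() > 0
        assert ring.shape == label_map.shape

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError, match="99"):
            membrane_ring(np.ones((8, 8), dtype=int), 99)

    def test_neighbor_interior_retained(self):
        """Ring pixels inside an adjacent cell are kept, not masked out."""
        label_map = np.zeros((20, 20), dtype=int)
        label_map[5:15, 2:9] = 1
        label_map[5:15, 10:17] = 2
        ring = membrane_ring(label_map, 1, ring_width=2)
        assert (ring & (label_map == 2)).sum() > 0


class TestScoreCell:
    def _ring_and_stain(self, n_ring, n_stained):
        ring = np.zeros((1, n_ring + 4), dtype=bool)
        ring[0, :n_ring] = True
        stain = np.zeros_like(ring)
        stain[0, :n_stained] = True
        return ring, stain

    @pytest.mark.parametrize(
        "n_ring, n_stained, expected",
        [(100, 31, True), (100, 30, False), (100, 0, False), (10, 10, True)],
    )
    def test_fraction_boundary(self, n_ring, n_stained, expected):
        ring, stain = self._ring_and_stain(n_ring, n_stained)
        score = score_cell(ring, stain)
        assert score.stained_fraction == n_stained / n_ring
        assert score.is_cls is expected

    def test_empty_ring_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_cell(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))


class TestFieldPercentage:
    def _cells(self, n, passed=True):
        return [
            CellRecord(i + 1, 100, 100.0, (0, 0), False, passed) for i in range(n)
        ]

    def _scores(self, flags):
        from adipoquant import ClsScore

        return [
            ClsScore(i + 1, 100, 31 if f else 0, 0.31 if f else 0.0, f)
            for i, f in enumerate(flags)
        ]

    def test_simple_percentage(self):
        cells = self._cells(12)
        scores = self._scores([True] * 3 + [False] * 9)
        assert field_cls_percentage(scores, cells) == 25.0

    def test_zero_cls_is_zero_percent(self):
        cells = self._cells(7)
        assert field_cls_percentage(self._scores([False] * 7), cells) == 0.0

    def test_no_passing_cells_is_an_error(self):
        cells = self._cells(3, passed=False)
        with pytest.raises(ValueError, match="undefined"):
            field_cls_percentage(self._scores([False] * 3), cells)


class TestInvariances:
    def test_translation_leaves_fractions_unchanged(self, clean_field):
        _, image, _ = clean_field
        seg = segment_field(image)
        scores = {s.label: s.stained_fraction for s in score_field(image.rgb, seg)}

        # shift the whole field by whole pixels, padding with background
        shifted = np.roll(image.rgb, (7, 5), axis=(0, 1))
        shifted_map = np.roll(seg.label_map, (7, 5), axis=(0, 1))
        from adipoquant.segmentation import SegmentationResult, measure_cells

        seg2 = SegmentationResult(
            label_map=shifted_map,
            cells=measure_cells(shifted_map, 1.0),
            threshold_used=seg.threshold_used,
        )
        scores2 = {s.label: s.stained_fraction for s in score_field(shifted, seg2)}
        # interior cells (away from the wrap seam) must score identically;
        # the border-touching background blob wraps and is excluded
        checked = 0
        for label, frac in scores.items():
            cell = seg.cell(label)
            if (
                cell.passed_filters
                and 30 < cell.centroid[0] < 220
                and 30 < cell.centroid[1] < 220
            ):
                assert scores2[label] == frac
                checked += 1
        assert checked > 0

    def test_fraction_threshold_monotonicity(self, clean_field):
        _, image, _ = clean_field
        seg = segment_field(image)
        pct = []
        for thr in (0.1, 0.3, 0.6, 0.9):
            scores = score_field(
                image.rgb, seg, ClsParams(membrane_fraction_threshold=thr)
            )
            pct.append(field_cls_percentage(scores, seg.cells))
        assert pct == sorted(pct, reverse=True)


class TestPlantedRecovery:
    def test_measured_fraction_tracks_planted(self, clean_field):
        """Planted fraction 0.50, noise-free: measured within 0.02."""
        _, image, truth = clean_field
        seg = segment_field(image)
        scores = {s.label: s for s in score_field(image.rgb, seg)}
        mapping = match_truth_to_segmentation(truth, seg)
        for cell in truth.cells:
            measured = scores[mapping[cell.label]].stained_fraction
            assert measured == pytest.approx(0.50, abs=0.02)

    def test_classification_exact_away_from_boundary(self):
        """100% per-cell accuracy at noise sd 2, fractions outside [0.25, 0.35]."""
        config = noise_free(
            seed=19,
            cls_fraction=0.5,
            stained_membrane_fraction_dist=(0.40, 0.90),
            background_stain_fraction_dist=(0.0, 0.15),
            lumen_intensity=(210.0, 2.0),
            membrane_intensity=(60.0, 2.0),
            background_intensity=(180.0, 2.0),
        )
        image, truth = generate_field(config)
        seg = segment_field(image)
        scores = {s.label: s for s in score_field(image.rgb, seg)}
        mapping = match_truth_to_segmentation(truth, seg)
        for cell in truth.cells:
            assert scores[mapping[cell.label]].is_cls == cell.is_cls_true
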