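"""Duplicate-detection removal: the IOB/BOU containment rule vs NMS."""

import numpy as np
import pytest

from paniclecount.boxgeom import Box, bou, iob, iou
from paniclecount.suppress import (
    SuppressionConfig,
    SuppressionConfigError,
    brute_force_dedup,
    nms,
    remove_repeats_iob_bou,
    suppress,
)
from .conftest import random_boxes

CFG = SuppressionConfig()  # iob_bou, 0.8/0.8


class TestIobBouRule:
    def test_identical_pair_keeps_one(self):
        boxes = [Box(0, 0, 10, 10), Box(0, 0, 10, 10)]
        assert len(remove_repeats_iob_bou(boxes, CFG)) == 1

    def test_contained_small_box_removed(self):
        big = Box(0, 0, 100, 100)
        small = Box(10, 10, 30, 30)
        kept = remove_repeats_iob_bou([small, big], CFG)
        assert kept == [big]

    def test_distinct_overlapping_panicles_both_kept(self):
        a = Box(0, 0, 50, 50)
        b = Box(40, 40, 90, 90)
        assert iob(a, b) == pytest.approx(100 / 2500)
        kept = remove_repeats_iob_bou([a, b], CFG)
        assert kept == [a, b]

    def test_retained_pairs_never_violate_rule(self, rng):
        for _ in range(50):
            boxes = random_boxes(rng, int(rng.integers(2, 20)))
            kept = remove_repeats_iob_bou(boxes, CFG)
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    assert not (
                        iob(kept[i], kept[j]) > CFG.iob_threshold
                        and bou(kept[i], kept[j]) > CFG.bou_threshold
                    )

    def test_output_order_stable_and_subset(self, rng):
        boxes = random_boxes(rng, 15)
        kept = remove_repeats_iob_bou(boxes, CFG)
        positions = [boxes.index(k) for k in kept]
        assert positions == sorted(positions)
        assert all(k in boxes for k in kept)


class TestNms:
    def test_identical_pair_keeps_one(self):
        cfg = SuppressionConfig(method="nms_iou", nms_threshold=0.5)
        boxes = [Box(0, 0, 10, 10, score=0.9), Box(0, 0, 10, 10, score=0.8)]
        assert len(nms(boxes, cfg)) == 1

    def test_contained_small_box_survives_iou_nms(self):
        """The baseline failure mode: containment with large area ratio
        gives low IoU, so IoU-NMS keeps the duplicate."""
        cfg = SuppressionConfig(method="nms_iou", nms_threshold=0.5)
        big = Box(0, 0, 100, 100, score=0.9)
        small = Box(10, 10, 30, 30, score=0.8)
        assert iou(big, small) == pytest.approx(0.04)
        assert len(nms([big, small], cfg)) == 2

    def test_half_overlap_suppressed(self):
        cfg = SuppressionConfig(method="nms_iou", nms_threshold=0.3)
        a = Box(0, 0, 10, 10, score=0.9)
        b = Box(5, 0, 15, 10, score=0.5)
        assert iou(a, b) == pytest.approx(1 / 3)
        assert nms([a, b], cfg) == [a]

    @pytest.mark.parametrize("method", ["nms_iou", "nms_giou", "nms_diou"])
    def test_all_metrics_dedupe_identical_boxes(self, method):
        cfg = SuppressionConfig(method=method, nms_threshold=0.5)
        boxes = [Box(0, 0, 10, 10, score=0.9), Box(0, 0, 10, 10, score=0.8)]
        assert len(nms(boxes, cfg)) == 1

    def test_area_order_fallback_without_scores(self):
        cfg = SuppressionConfig(method="nms_iou", nms_threshold=0.5)
        big = Box(0, 0, 10, 10)
        near = Box(0, 0, 10, 9)
        assert nms([near, big], cfg) == [big]


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sets(self, rng):
        """Greedy largest-first removal reaches the same fixed point as
        exhaustive pair scanning on 500 random mixed-scale box sets."""
        for _ in range(500):
            boxes = random_boxes(rng, int(rng.integers(0, 21)))
            assert remove_repeats_iob_bou(boxes, CFG) == brute_force_dedup(boxes, CFG)

    def test_empty_input(self):
        assert brute_force_dedup([], CFG) == []
        assert remove_repeats_iob_bou([], CFG) == []


class TestContainmentSeparation:
    def test_iob_bou_removes_what_iou_nms_keeps(self, rng):
        """Contained duplicates with >= 10x area ratio: the containment
        rule removes them, IoU-NMS at 0.5 does not."""
        nms_cfg = SuppressionConfig(method="nms_iou", nms_threshold=0.5)
        for _ in range(100):
            w = rng.uniform(100, 200)
            h = rng.uniform(100, 200)
            big = Box(0, 0, w, h, score=0.9)
            # contained box with at most 1/10 of the big box's area
            sw = rng.uniform(10, w / 2)
            sh = rng.uniform(5, min(w * h / 10 / sw, h))
            x = rng.uniform(0, w - sw)
            y = rng.uniform(0, h - sh)
            small = Box(x, y, x + sw, y + sh, score=0.8)
            assert big.area / small.area >= 10 * 0.999
            assert len(remove_repeats_iob_bou([big, small], CFG)) == 1
            assert len(nms([big, small], nms_cfg)) == 2


class TestGenericProperties:
    @pytest.mark.parametrize(
        "cfg",
        [
            CFG,
            SuppressionConfig(method="nms_iou", nms_threshold=0.5),
            SuppressionConfig(method="nms_giou", nms_threshold=0.5),
            SuppressionConfig(method="nms_diou", nms_threshold=0.5),
        ],
    )
    def test_idempotent_and_conservative(self, cfg, rng):
        for _ in range(30):
            boxes = random_boxes(rng, int(rng.integers(0, 15)))
            once = suppress(boxes, cfg)
            assert suppress(once, cfg) == once
            assert all(b in boxes for b in once)

    def test_invalid_config_rejected(self):
        with pytest.raises(SuppressionConfigError):
            SuppressionConfig(method="soft_nms")
        with pytest.raises(SuppressionConfigError):
            SuppressionConfig(iob_threshold=1.5)
        with pytest.raises(SuppressionConfigError):
            SuppressionConfig(nms_threshold=-2.0)
        with pytest.raises(SuppressionConfigError):
            nms([], CFG)  # iob_bou is not an NMS method
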