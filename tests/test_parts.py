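"""Activation stretching, anchor scoring, NMS, and part-crop extraction."""

import warnings

import numpy as np
import pytest

from boneage.localization import RoIBox
from boneage.parts import (
    AnchorConfig,
    ScoredRegion,
    extract_parts,
    generate_anchors,
    iou,
    minmax_normalize,
    nms,
    propose_parts,
    score_regions,
    stretch_map,
    top_n_parts,
)


class TestMinMax:
    def test_affine_endpoints(self):
        assert np.allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                           [0.0, 0.5, 1.0])

    def test_constant_degenerate_convention(self):
        assert np.allclose(minmax_normalize(np.full(3, 5.0)), 0.0)

    def test_range_contract(self, rng):
        z = minmax_normalize(rng.normal(size=(7, 7)))
        assert z.min() == 0.0 and z.max() == 1.0


class TestStretch:
    def test_peak_location_invariant(self, rng):
        a = rng.normal(size=(9, 9))
        s = stretch_map(a, eta=4.0)
        assert np.argmax(s) == np.argmax(a)

    def test_hand_evaluated_values(self):
        # z(A) = [0, 0.5, 1], eta=2 -> z(exp([0,1,2])) = [0, (e-1)/(e^2-1), 1]
        a = np.array([0.0, 0.5, 1.0])
        expected = np.array([0.0, (np.e - 1) / (np.e ** 2 - 1), 1.0])
        assert np.allclose(stretch_map(a, eta=2.0), expected, atol=1e-12)

    def test_midvalue_contrast_increases_with_eta(self):
        a = np.array([0.0, 0.5, 1.0])
        mids = [stretch_map(a, eta)[1] for eta in (1.0, 2.0, 4.0, 8.0)]
        assert all(x > y for x, y in zip(mids[:-1], mids[1:]))

    def test_eta_domain(self):
        with pytest.raises(ValueError):
            stretch_map(np.eye(3), eta=0.0)


class TestAnchors:
    def test_fifteen_groups_per_interior_point(self):
        cfg = AnchorConfig(stride=64)  # lattice 32, 96, ..., 288, ... on 576
        boxes = generate_anchors((576, 576), cfg)
        center = [b for b in boxes
                  if abs((b.x0 + b.x1) / 2 - 288) <= 1
                  and abs((b.y0 + b.y1) / 2 - 288) <= 1]
        assert len(center) == len(cfg.ratios) * len(cfg.scales) == 15

    def test_centered_square_arithmetic(self):
        boxes = generate_anchors((576, 576), AnchorConfig(stride=64))
        assert RoIBox(224, 224, 352, 352) in boxes

    def test_all_boxes_inside_frame(self):
        for b in generate_anchors((576, 576), AnchorConfig()):
            assert 0 <= b.x0 < b.x1 <= 576 and 0 <= b.y0 < b.y1 <= 576

    def test_scales_shrink_with_frame(self):
        small = generate_anchors((96, 96), AnchorConfig())
        assert small and max(b.width for b in small) <= 96


def score_oracle(values, box):
    total = 0.0
    for y in range(box.y0, box.y1):
        for x in range(box.x0, box.x1):
            total += values[y, x]
    return total / box.area


class TestScoring:
    def test_mean_of_ones(self):
        s = np.ones((10, 10))
        [r] = score_regions(s, [RoIBox(2, 2, 8, 8)])
        assert r.score == pytest.approx(1.0)

    def test_half_and_half(self):
        s = np.zeros((4, 4))
        s[:, 2:] = 1.0
        [r] = score_regions(s, [RoIBox(0, 0, 4, 4)])
        assert r.score == pytest.approx(0.5)

    def test_summed_area_matches_brute_force(self, rng):
        for _ in range(100):
            s = rng.random((12, 15))
            x0, y0 = rng.integers(0, 10), rng.integers(0, 8)
            box = RoIBox(int(x0), int(y0),
                         int(rng.integers(x0 + 1, 16)),
                         int(rng.integers(y0 + 1, 13)))
            [r] = score_regions(s, [box])
            assert r.score == pytest.approx(score_oracle(s, box), abs=1e-6)


def nms_oracle(regions, threshold):
    """Exhaustive greedy suppression with naive IoU loops."""
    remaining = sorted(range(len(regions)),
                       key=lambda i: (-regions[i].score, i))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(regions[best])
        remaining = [j for j in remaining
                     if iou(regions[best].box, regions[j].box) <= threshold]
    return kept


class TestNMS:
    def test_identical_boxes_keep_highest(self):
        b = RoIBox(0, 0, 4, 4)
        out = nms([ScoredRegion(b, 0.9), ScoredRegion(b, 0.8)], 0.5)
        assert len(out) == 1 and out[0].score == 0.9

    def test_disjoint_all_survive_sorted(self):
        rs = [ScoredRegion(RoIBox(0, 0, 2, 2), 0.3),
              ScoredRegion(RoIBox(10, 10, 12, 12), 0.9),
              ScoredRegion(RoIBox(20, 0, 22, 2), 0.6)]
        out = nms(rs, 0.25)
        assert [r.score for r in out] == [0.9, 0.6, 0.3]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            regions = []
            for _ in range(rng.integers(1, 21)):
                x0, y0 = rng.integers(0, 20, size=2)
                regions.append(ScoredRegion(
                    RoIBox(int(x0), int(y0),
                           int(x0 + rng.integers(1, 10)),
                           int(y0 + rng.integers(1, 10))),
                    float(rng.random())))
            for thr in (0.1, 0.3, 0.5):
                assert nms(regions, thr) == nms_oracle(regions, thr)

    def test_kept_boxes_form_iou_antichain(self, rng):
        regions = [ScoredRegion(RoIBox(int(x), int(y), int(x) + 6, int(y) + 6),
                                float(rng.random()))
                   for x, y in rng.integers(0, 20, size=(40, 2))]
        kept = nms(regions, 0.25)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert iou(a.box, b.box) <= 0.25


class TestTopN:
    def test_top_three_of_five(self):
        rs = [ScoredRegion(RoIBox(i, 0, i + 1, 1), s)
              for i, s in enumerate([0.2, 0.9, 0.5, 0.7, 0.1])]
        out = top_n_parts(rs, 3)
        assert [r.score for r in out] == [0.9, 0.7, 0.5]

    def test_tie_breaks_stable(self):
        rs = [ScoredRegion(RoIBox(i, 0, i + 1, 1), 0.5) for i in range(4)]
        out = top_n_parts(rs, 2)
        assert [r.box.x0 for r in out] == [0, 1]

    def test_scores_non_increasing(self, rng):
        rs = [ScoredRegion(RoIBox(int(i), 0, int(i) + 1, 1), float(s))
              for i, s in enumerate(rng.random(20))]
        out = top_n_parts(rs, 8)
        assert all(a.score >= b.score for a, b in zip(out[:-1], out[1:]))

    def test_shortfall_warns(self):
        rs = [ScoredRegion(RoIBox(0, 0, 1, 1), 0.5)]
        with pytest.warns(UserWarning):
            out = top_n_parts(rs, 3)
        assert len(out) == 1


class TestExtract:
    def test_count_and_size(self, rng):
        img = rng.random((64, 64))
        rs = [ScoredRegion(RoIBox(0, 0, 32, 32), 1.0),
              ScoredRegion(RoIBox(16, 16, 48, 48), 0.5)]
        crops = extract_parts(img, rs, out_size=(288, 288))
        assert len(crops) == 2
        assert all(c.shape == (288, 288) for c in crops)

    def test_constant_image_constant_crops(self):
        img = np.full((32, 32), 0.3)
        [crop] = extract_parts(img, [ScoredRegion(RoIBox(4, 4, 20, 20), 1.0)],
                               out_size=(16, 16))
        assert np.allclose(crop, 0.3)


def two_bump_map(size, tall, short, h_tall=1.0, h_short=0.6, width=4.0):
    yy, xx = np.mgrid[0:size, 0:size]
    a = h_tall * np.exp(-((yy - tall[0]) ** 2 + (xx - tall[1]) ** 2) / width)
    a += h_short * np.exp(-((yy - short[0]) ** 2 + (xx - short[1]) ** 2) / width)
    return a


class TestPeakRetention:
    @pytest.mark.parametrize("eta", [2.0, 4.0, 8.0])
    def test_taller_bump_outscores_distant_boxes(self, eta):
        a = two_bump_map(48, tall=(12, 12), short=(34, 34))
        s = stretch_map(a, eta)
        side = 10
        def box_at(cy, cx):
            return RoIBox(cx - side // 2, cy - side // 2,
                          cx + side // 2, cy + side // 2)
        [peak] = score_regions(s, [box_at(12, 12)])
        for cy in range(side // 2, 48 - side // 2, 4):
            for cx in range(side // 2, 48 - side // 2, 4):
                if max(abs(cy - 12), abs(cx - 12)) < side:
                    continue  # closer than one box-width
                [other] = score_regions(s, [box_at(cy, cx)])
                assert peak.score > other.score


class TestProposePipeline:
    def test_deterministic(self, rng):
        channel = rng.random((6, 6))
        r1, _ = propose_parts(channel, frame=96)
        r2, _ = propose_parts(channel, frame=96)
        assert r1 == r2

    def test_matches_composed_public_operations(self, rng):
        from boneage.localization import resize_bilinear

        channel = rng.random((6, 6))
        cfg = AnchorConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fast, stretched = propose_parts(channel, eta=4.0, n_parts=4,
                                            iou_threshold=0.25, frame=96,
                                            cfg=cfg)
            resized = resize_bilinear(channel, (96, 96))
            slow_s = stretch_map(resized, 4.0)
            scored = score_regions(slow_s, generate_anchors((96, 96), cfg))
            slow = top_n_parts(nms(scored, 0.25), 4)
        assert np.allclose(stretched, slow_s)
        assert [r.box for r in fast] == [r.box for r in slow]
        assert np.allclose([r.score for r in fast], [r.score for r in slow])

    def test_returned_scores_non_increasing(self, rng):
        regions, _ = propose_parts(rng.random((6, 6)), frame=96)
        scores = [r.score for r in regions]
        assert scores == sorted(scores, reverse=True)
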