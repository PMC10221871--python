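"""CAM projection/pooling, thresholded masks, and hand-box extraction."""

import warnings

import numpy as np
import pytest

from boneage.localization import (
    BinaryMask,
    RoIBox,
    crop_and_resize,
    global_pool,
    make_mask,
    mask_to_box,
    project_features,
    select_channel,
    softmax_probs,
)


def project_oracle(features, weights):
    """Brute-force triple loop for the 1x1 projection."""
    h, w, k = features.shape
    c = weights.shape[1]
    out = np.zeros((h, w, c))
    for i in range(h):
        for j in range(w):
            for cc in range(c):
                out[i, j, cc] = sum(weights[kk, cc] * features[i, j, kk]
                                    for kk in range(k))
    return out


class TestProjection:
    def test_constant_input_linearity(self):
        f = np.ones((3, 3, 2))
        w = np.array([[1.0], [2.0]])
        assert np.allclose(project_features(f, w), 3.0)

    def test_zero_weights(self, rng):
        f = rng.normal(size=(4, 4, 3))
        assert np.allclose(project_features(f, np.zeros((3, 5))), 0.0)

    def test_matches_brute_force(self, rng):
        f = rng.normal(size=(4, 4, 3))
        w = rng.normal(size=(3, 6))
        assert np.allclose(project_features(f, w), project_oracle(f, w),
                           atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            project_features(rng.normal(size=(4, 4, 3)),
                             rng.normal(size=(5, 6)))


class TestPooling:
    def test_constant_channel(self):
        a = np.full((5, 7, 2), 3.5)
        assert np.allclose(global_pool(a), 3.5)

    def test_small_mean(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert global_pool(a)[0] == pytest.approx(2.5)

    def test_matches_double_loop(self, rng):
        a = rng.normal(size=(6, 6, 240))
        naive = np.array([sum(a[i, j, c] for i in range(6) for j in range(6)) / 36
                          for c in range(240)])
        assert np.allclose(global_pool(a), naive, atol=1e-9)

    def test_cam_consistency_with_projection(self, rng):
        # pooling commutes with the linear 1x1 projection
        f = rng.normal(size=(5, 5, 8))
        w = rng.normal(size=(8, 12))
        lhs = global_pool(project_features(f, w))
        rhs = f.mean(axis=(0, 1)) @ w
        assert np.allclose(lhs, rhs, atol=1e-6)


class TestSoftmax:
    def test_uniform_on_equal_scores(self):
        p = softmax_probs(np.zeros(240))
        assert np.allclose(p, 1 / 240)

    def test_closed_form_two_classes(self):
        assert np.allclose(softmax_probs(np.array([0.0, np.log(3)])),
                           [0.25, 0.75])

    def test_shift_invariance_and_unit_sum(self, rng):
        s = rng.normal(size=240) * 50
        p = softmax_probs(s)
        assert np.allclose(p, softmax_probs(s + 123.4), atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_overflow_safe(self):
        p = softmax_probs(np.array([1e4, 1e4 - 1]))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestSelectChannel:
    def test_one_hot(self):
        p = np.zeros(240)
        p[150] = 1.0
        assert select_channel(p) == 150

    def test_uniform_ties_to_lowest(self):
        assert select_channel(np.full(240, 1 / 240)) == 0

    def test_matches_scan(self, rng):
        s = rng.normal(size=240)
        assert select_channel(softmax_probs(s)) == int(np.argmax(s))


class TestMask:
    def test_threshold_on_normalised_values(self):
        channel = np.array([[0.0, 0.5], [0.7, 1.0]])  # already spans [0,1]
        mask = make_mask(channel, tau=0.6)
        assert mask.values.tolist() == [[0, 0], [1, 1]]

    def test_small_tau_keeps_everything_above_minimum(self, rng):
        channel = rng.normal(size=(8, 8))
        mask = make_mask(channel, tau=1e-6)
        assert mask.values.sum() >= 63  # only the exact minimum can fall below

    def test_nested_in_tau(self, rng):
        channel = rng.normal(size=(10, 10))
        loose = make_mask(channel, 0.4).values
        tight = make_mask(channel, 0.8).values
        assert np.all(tight <= loose)

    def test_monotone_over_random_maps(self, rng):
        taus = [0.2, 0.4, 0.6, 0.8]
        for _ in range(100):
            channel = rng.normal(size=(6, 6))
            masks = [make_mask(channel, t).values for t in taus]
            for a, b in zip(masks[:-1], masks[1:]):
                assert np.all(b <= a)

    def test_constant_channel_degenerates(self):
        with pytest.warns(UserWarning):
            mask = make_mask(np.full((4, 4), 2.0), 0.6)
        assert mask.degenerate and mask.values.sum() == 0

    def test_tau_domain(self):
        with pytest.raises(ValueError):
            make_mask(np.eye(3), 1.5)


def flood_fill_oracle(values):
    """Exhaustive 8-connected component labelling; returns largest's bbox."""
    h, w = values.shape
    seen = np.zeros_like(values, dtype=bool)
    best = None
    for sy in range(h):
        for sx in range(w):
            if values[sy, sx] and not seen[sy, sx]:
                stack, comp = [(sy, sx)], []
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and values[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                if best is None or len(comp) > len(best):
                    best = comp
    ys = [y for y, _ in best]
    xs = [x for _, x in best]
    return min(xs), min(ys), max(xs) + 1, max(ys) + 1


class TestMaskToBox:
    def test_single_pixel(self):
        values = np.zeros((8, 8), dtype=np.uint8)
        values[3, 5] = 1
        box = mask_to_box(BinaryMask(values, 0.6))
        assert (box.x0, box.y0, box.x1, box.y1) == (5, 3, 6, 4)

    def test_largest_component_wins(self):
        values = np.zeros((8, 8), dtype=np.uint8)
        values[0:2, 0:3] = 1  # 6 pixels
        values[6:7, 6:8] = 1  # 2 pixels
        box = mask_to_box(BinaryMask(values, 0.6))
        assert (box.x0, box.y0, box.x1, box.y1) == (0, 0, 3, 2)

    def test_empty_mask_returns_none(self):
        assert mask_to_box(BinaryMask(np.zeros((4, 4), dtype=np.uint8), 0.6)) is None

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            values = (rng.random((9, 9)) < 0.35).astype(np.uint8)
            if not values.any():
                continue
            box = mask_to_box(BinaryMask(values, 0.6))
            assert (box.x0, box.y0, box.x1, box.y1) == flood_fill_oracle(values)

    @pytest.mark.parametrize("tau", [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    def test_gaussian_bump_box_contains_peak(self, tau):
        yy, xx = np.mgrid[0:16, 0:16]
        i0, j0 = 11, 4
        bump = np.exp(-((yy - i0) ** 2 + (xx - j0) ** 2) / 8.0)
        box = mask_to_box(make_mask(bump, tau))
        assert box.x0 <= j0 < box.x1 and box.y0 <= i0 < box.y1


def bilinear_oracle(image, ys, xs):
    """Hand-rolled edge-clamped bilinear sampling at fractional coords."""
    h, w = image.shape
    out = np.zeros((len(ys), len(xs)))
    for a, y in enumerate(ys):
        for b, x in enumerate(xs):
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - y0, x - x0
            def at(i, j):
                return image[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]
            out[a, b] = ((1 - fy) * (1 - fx) * at(y0, x0)
                         + (1 - fy) * fx * at(y0, x0 + 1)
                         + fy * (1 - fx) * at(y0 + 1, x0)
                         + fy * fx * at(y0 + 1, x0 + 1))
    return out


class TestCropAndResize:
    def test_full_box_identity(self, rng):
        img = rng.random((12, 10))
        box = RoIBox(0, 0, 10, 12, frame="source-image")
        out = crop_and_resize(img, box, out_size=(10, 12))
        assert np.allclose(out, img, atol=1e-12)

    def test_checkerboard_upsample_matches_hand_bilinear(self):
        img = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = crop_and_resize(img, RoIBox(0, 0, 2, 2, frame="source-image"),
                              out_size=(4, 4))
        coords = (np.arange(4) + 0.5) * 0.5 - 0.5
        assert np.allclose(out, bilinear_oracle(img, coords, coords), atol=1e-12)

    def test_constant_image_constant_output(self):
        img = np.full((8, 8), 0.7)
        out = crop_and_resize(img, RoIBox(1, 2, 5, 6, frame="source-image"),
                              out_size=(16, 16))
        assert np.allclose(out, 0.7)

    def test_out_of_bounds_clamped_with_warning(self, rng):
        img = rng.random((8, 8))
        with pytest.warns(UserWarning):
            out = crop_and_resize(img, RoIBox(4, 4, 12, 12, frame="source-image"),
                                  out_size=(4, 4))
        assert out.shape == (4, 4) and np.isfinite(out).all()


def test_box_invariants():
    with pytest.raises(ValueError):
        RoIBox(3, 3, 3, 5)
    b = RoIBox(1, 2, 4, 7)
    assert b.width == 3 and b.height == 5 and b.area == 15
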