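"""Segmentation tests: channel combination, preprocessing, region growth."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from calsig import segment as seg


def gaussian_blob(shape, cy, cx, sigma, amp=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


class TestCombineChannels:
    def test_constant_input_maps_to_zero(self):
        out = seg.combine_channels(np.full((8, 8), 0.2), np.full((8, 8), 0.3))
        assert np.all(out == 0.0)

    def test_minmax_endpoints(self):
        red = np.zeros((8, 8))
        red[3, 4] = 10.0
        out = seg.combine_channels(red, np.zeros((8, 8)))
        assert out[3, 4] == 1.0
        out[3, 4] = 0.0
        assert np.all(out == 0.0)

    def test_cells_brighter_than_background(self, rendered_monolayer):
        seq, layout = rendered_monolayer
        out = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
        fg = []
        for c in layout.cells:
            x, y = int(c.centroid_px[0]), int(c.centroid_px[1])
            fg.append(out[y, x])
        bg_mask = np.ones(out.shape, bool)
        for c in layout.cells:
            x, y = c.centroid_px
            yy, xx = np.mgrid[0:out.shape[0], 0:out.shape[1]]
            bg_mask &= (yy - y) ** 2 + (xx - x) ** 2 > (c.radius_px + 3) ** 2
        assert np.mean(fg) > out[bg_mask].mean()

    def test_shape_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            seg.combine_channels(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            seg.combine_channels(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)))


class TestPreprocess:
    def test_uniform_image_survives_local_mean(self):
        p = seg.SegmentationParams(blur_sigma_px=0.0, mask_threshold=0.1,
                                   localmean_window_px=5,
                                   localmean_fraction=0.9)
        out = seg.preprocess(np.full((32, 32), 0.5), p)
        assert np.allclose(out, 0.5)

    def test_ridge_between_blobs_is_zeroed(self):
        # two broad cells joined by a dimmer ridge at 40% of the peak:
        # with a window spanning both, the ridge falls below 0.8 x the
        # local mean while the cores stay above it
        img = np.zeros((61, 61))
        yy, xx = np.mgrid[0:61, 0:61]
        for cx in (14, 46):
            img[(yy - 30) ** 2 + (xx - cx) ** 2 <= 13 ** 2] = 1.0
        ridge = (np.abs(yy - 30) <= 1) & (img < 0.5)
        img[ridge] = 0.4
        p = seg.SegmentationParams(blur_sigma_px=0.0, mask_threshold=0.05,
                                   localmean_window_px=31,
                                   localmean_fraction=0.8)
        out = seg.preprocess(img, p)
        assert out[30, 30] == 0.0          # ridge suppressed
        assert out[30, 14] > 0.5 and out[30, 46] > 0.5   # cores retained

    def test_all_below_threshold_gives_zero(self):
        p = seg.SegmentationParams(mask_threshold=0.5)
        out = seg.preprocess(np.full((32, 32), 0.1), p)
        assert np.all(out == 0.0)

    def test_window_larger_than_image_raises(self):
        p = seg.SegmentationParams(localmean_window_px=64)
        with pytest.raises(ValueError):
            seg.preprocess(np.zeros((32, 32)), p)


class TestExtractROIs:
    def test_single_blob_single_roi(self):
        # idealized blob on a zero background: stop level 0.3
        img = gaussian_blob((64, 64), 32, 32, 6)
        p = seg.SegmentationParams(min_size_px=5, max_size_px=4000,
                                   mask_threshold=0.3)
        rm = seg.extract_rois(img, p)
        assert len(rm) == 1
        assert rm.labels[32, 32] == rm.rois[0].id

    def test_blob_grid_one_seed_each(self):
        img = np.zeros((350, 350))
        centers = [(35 + 70 * i, 35 + 70 * j) for i in range(5)
                   for j in range(5)]
        for cy, cx in centers:
            img += gaussian_blob(img.shape, cy, cx, 6)
        p = seg.SegmentationParams(min_size_px=5, max_size_px=4000,
                                   max_radius_px=30, mask_threshold=0.3)
        rm = seg.extract_rois(img, p)
        assert len(rm) == 25
        seeds = {(r.seed_px[1] // 70, r.seed_px[0] // 70) for r in rm.rois}
        assert len(seeds) == 25

    def test_empty_image_empty_map(self):
        rm = seg.extract_rois(np.zeros((32, 32)))
        assert len(rm) == 0 and np.all(rm.labels == 0)

    def test_invariants_on_grid(self):
        img = np.zeros((210, 210))
        for cy, cx in [(35 + 70 * i, 35 + 70 * j) for i in range(3)
                       for j in range(3)]:
            img += gaussian_blob(img.shape, cy, cx, 6)
        p = seg.SegmentationParams(min_size_px=5, max_size_px=4000)
        rm = seg.extract_rois(img, p)
        for roi in rm.rois:
            mask = rm.mask(roi.id)
            # single connected component
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n == 1
            # within max radius of the seed
            yy, xx = np.nonzero(mask)
            sx, sy = roi.seed_px
            assert (((yy - sy) ** 2 + (xx - sx) ** 2)
                    <= p.max_radius_px ** 2).all()
            # watershed containment at extraction time
            assert img[mask].min() >= p.roi_threshold_fraction * img[sy, sx] \
                - 1e-12
            assert p.min_size_px <= roi.pixel_count <= p.max_size_px

    def test_determinism(self, rendered_monolayer):
        seq, _ = rendered_monolayer
        comb = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
        prep = seg.preprocess(comb)
        a = seg.extract_rois(prep)
        b = seg.extract_rois(prep)
        assert np.array_equal(a.labels, b.labels)
        assert [r.seed_px for r in a.rois] == [r.seed_px for r in b.rois]

    def test_monolayer_recall_and_precision(self, rendered_monolayer):
        seq, layout = rendered_monolayer
        comb = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
        rm = seg.extract_rois(seg.preprocess(comb))
        rec, prec, _ = seg.score_segmentation(rm, layout, 5.0)
        assert rec >= 0.95 and prec >= 0.95


class TestReview:
    @pytest.fixture()
    def roimap(self):
        img = np.zeros((210, 210))
        for cy, cx in [(35 + 70 * i, 35 + 70 * j) for i in range(3)
                       for j in range(3)]:
            img += gaussian_blob(img.shape, cy, cx, 6)
        return seg.extract_rois(
            img, seg.SegmentationParams(min_size_px=5, max_size_px=4000))

    def test_empty_rejection_is_identity(self, roimap):
        out = seg.review_rois(roimap, [])
        assert np.array_equal(out.labels, roimap.labels)
        assert out.ids == roimap.ids

    def test_reject_one_keeps_others(self, roimap):
        victim = roimap.ids[0]
        out = seg.review_rois(roimap, [victim])
        assert len(out) == len(roimap) - 1
        keep = roimap.labels.copy()
        keep[keep == victim] = 0
        assert np.array_equal(out.labels, keep)

    def test_reject_all(self, roimap):
        out = seg.review_rois(roimap, roimap.ids)
        assert len(out) == 0 and np.all(out.labels == 0)

    def test_unknown_id(self, roimap):
        with pytest.raises(KeyError):
            seg.review_rois(roimap, [9999])


class TestScore:
    def _layout(self, pts):
        from calsig import synth
        p = synth.TransientParams()
        return synth.CellLayout((300, 300), 0.65,
                                [synth.Cell(xy, 5.0, p, "1a") for xy in pts])

    def _roimap(self, pts):
        rois = [seg.ROI(i + 1, (int(x), int(y)), 10, (x, y))
                for i, (x, y) in enumerate(pts)]
        return seg.ROIMap(np.zeros((300, 300), np.int32), rois)

    def test_perfect_match(self):
        pts = [(20.0 + 50 * i, 20.0) for i in range(5)]
        rec, prec, rmse = seg.score_segmentation(self._roimap(pts),
                                                 self._layout(pts), 5.0)
        assert rec == 1.0 and prec == 1.0 and rmse == 0.0

    def test_partial_recall(self):
        true = [(20.0 + 11 * i, 20.0 + 11 * (i % 3)) for i in range(25)]
        det = true[:24]
        rec, prec, _ = seg.score_segmentation(self._roimap(det),
                                              self._layout(true), 5.0)
        assert rec == pytest.approx(0.96)
        assert prec == 1.0

    def test_greedy_matches_optimal_when_spaced(self):
        """Exhaustive assignment oracle on <= 6 well-separated cells."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 7))
            true = [(30.0 + 40 * i, 30.0 + 10 * rng.random())
                    for i in range(n)]
            det = [(x + rng.normal(0, 1), y + rng.normal(0, 1))
                   for x, y in true]
            rec, prec, rmse = seg.score_segmentation(
                self._roimap(det), self._layout(true), 5.0)
            # brute force over all one-to-one assignments
            best = 0
            for perm in itertools.permutations(range(n)):
                ok = sum(np.hypot(det[i][0] - true[j][0],
                                  det[i][1] - true[j][1]) <= 5.0
                         for i, j in enumerate(perm))
                best = max(best, ok)
            assert rec == pytest.approx(best / n)
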