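"""Hue thresholding, morphological cleanup, shape matching and target selection."""

import numpy as np
import pytest
from skimage import measure

from calfdepth.contours import Contour, extract_contours, hu_log_moments, shape_score
from calfdepth.depth_io import DepthScene, ValidationError
from calfdepth.synthetic_data import CalfShapeParams, SceneConfig, render_scene
from calfdepth.threshold_segmentation import (
    SegmentationParams,
    SegmentationStatus,
    binarize,
    clean_mask,
    hue_channel,
    segment,
    select_target,
)


def make_scene(color):
    color = np.asarray(color, dtype=np.uint8)
    return DepthScene(depth=np.full(color.shape[:2], 1510.0), color=color)


class TestHueChannel:
    def test_pure_red_is_hue_zero(self):
        color = np.zeros((4, 4, 3), dtype=np.uint8)
        color[..., 0] = 255
        assert hue_channel(make_scene(color)).max() == 0

    def test_constant_color_gives_constant_hue(self):
        color = np.tile(np.array([10, 200, 60], dtype=np.uint8), (5, 5, 1))
        hue = hue_channel(make_scene(color))
        assert np.ptp(hue) == 0

    def test_scene_floor_below_threshold_calf_above(self, clean_scene):
        scene, mask = clean_scene
        hue = hue_channel(scene)
        calf = mask.astype(bool)
        assert hue[calf].min() > 60
        assert np.median(hue[~calf]) < 60

    def test_missing_color_rejected(self):
        scene = make_scene(np.zeros((4, 4, 3), dtype=np.uint8))
        scene.color = np.zeros((4, 4))  # degrade after construction
        with pytest.raises(ValidationError):
            hue_channel(scene)


class TestBinarize:
    def test_strictly_above_is_foreground(self):
        assert binarize(np.array([[61.0]]), 60)[0, 0] == 1

    def test_equal_goes_to_background(self):
        assert binarize(np.array([[60.0]]), 60)[0, 0] == 0

    def test_all_zero_hue_gives_empty_mask(self):
        assert binarize(np.zeros((3, 3)), 60).sum() == 0

    def test_monotone_in_threshold(self, rng):
        hue = rng.uniform(0, 179, size=(40, 40))
        prev = binarize(hue, 0)
        for thr in (30, 60, 90, 179):
            cur = binarize(hue, thr)
            assert not np.any(cur > prev)  # raising threshold never adds pixels
            prev = cur


class TestCleanMask:
    def test_interior_hole_removed(self):
        mask = np.zeros((500, 500), dtype=np.uint8)
        mask[50:450, 50:450] = 1
        mask[200:203, 200:203] = 0
        cleaned = clean_mask(mask)
        assert cleaned.sum() == 400 * 400

    def test_isolated_speck_removed(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[10, 10] = 1
        assert clean_mask(mask).sum() == 0

    def test_empty_mask_stays_empty(self):
        assert clean_mask(np.zeros((20, 20), dtype=np.uint8)).sum() == 0

    def test_no_foreground_beyond_dilation_radius(self, rng):
        mask = (rng.random((80, 80)) > 0.6).astype(np.uint8)
        params = SegmentationParams(closing_kernel_px=5, opening_kernel_px=5)
        cleaned = clean_mask(mask, params)
        from scipy import ndimage

        reach = ndimage.binary_dilation(mask.astype(bool), np.ones((5, 5), bool))
        assert not np.any(cleaned.astype(bool) & ~reach)


class TestShapeScore:
    def test_identical_contour_scores_zero(self, template):
        assert shape_score(template, template) == 0.0

    def test_scale_invariance(self, template):
        halved = Contour(template.patch[::2, ::2])
        assert shape_score(template, halved) < 0.05

    def test_rotation_invariance(self, template):
        rotated = Contour(np.rot90(template.patch))
        assert shape_score(template, rotated) < 1e-6

    def test_thin_bar_rejected_against_template(self, template):
        bar = Contour(np.ones((10, 900), dtype=bool))
        assert shape_score(bar, template) > 0.8

    def test_degenerate_contour_scores_infinite(self, template):
        empty = Contour(np.zeros((5, 5), dtype=bool))
        assert shape_score(empty, template) == float("inf")

    def test_log_moments_match_skimage_oracle(self, template):
        img = template.patch.astype(float)
        hu = measure.moments_hu(measure.moments_normalized(measure.moments_central(img)))
        ours = hu_log_moments(template)
        ok = ~np.isnan(ours)
        np.testing.assert_allclose(
            ours[ok], np.sign(hu[ok]) * np.log10(np.abs(hu[ok])), rtol=1e-12
        )


class TestContour:
    def test_polygon_roundtrip_preserves_region(self, template):
        poly = template.polygon()
        rebuilt = Contour.from_polygon(poly)
        # sub-pixel boundary tracing: areas agree within the perimeter bound
        assert abs(rebuilt.area - template.area) < len(poly)

    def test_extract_splits_components(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:10, 2:10] = 1
        mask[20:28, 20:28] = 1
        parts = extract_contours(mask)
        assert [c.area for c in parts] == [64, 64]

    def test_to_mask_respects_offset(self):
        c = Contour(np.ones((3, 4), dtype=bool), offset=(5, 6))
        m = c.to_mask((20, 20))
        assert m.sum() == 12 and m[5, 6] == 1 and m[7, 9] == 1


def rect_contour(height, width, extra_arm_to=None):
    """A filled rectangle, optionally with a 1-px arm extending the long side."""
    if extra_arm_to is None:
        return Contour(np.ones((height, width), dtype=bool))
    patch = np.zeros((height, extra_arm_to), dtype=bool)
    patch[:, :width] = True
    patch[height // 2, :] = True
    return Contour(patch)


class TestSelectTarget:
    def params_for(self, contour):
        # template equal to the candidate shape: the shape filter passes
        # with score 0 and the area/bbox filters decide alone
        return SegmentationParams(template=Contour(contour.patch.copy()))

    def test_valid_contour_succeeds(self):
        c = rect_contour(500, 300)  # area 150k, bbox 300x500
        res = select_target([c], self.params_for(c))
        assert res.status is SegmentationStatus.SUCCESS
        assert res.contour is c

    def test_empty_list_is_no_contours(self, template):
        res = select_target([], SegmentationParams(template=template))
        assert res.status is SegmentationStatus.NO_CONTOURS
        assert res.contour is None

    def test_shape_filter_first(self, template):
        bar = Contour(np.ones((10, 900), dtype=bool))
        res = select_target([bar], SegmentationParams(template=template))
        assert res.status is SegmentationStatus.NO_MATCH

    def test_area_filter_before_bbox(self):
        c = rect_contour(100, 100)  # area 10k fails, bbox 100 also out of bounds
        res = select_target([c], self.params_for(c))
        assert res.status is SegmentationStatus.FAILED_AREA

    def test_bbox_filter_last(self):
        c = rect_contour(400, 250, extra_arm_to=1000)  # area ok, bbox length 1000
        res = select_target([c], self.params_for(c))
        assert res.status is SegmentationStatus.FAILED_BBOX

    def test_largest_survivor_wins(self):
        small = rect_contour(400, 300)
        big = rect_contour(450, 320)
        params = self.params_for(big)
        params = SegmentationParams(template=big, shape_score_max=5.0)
        res = select_target([small, big], params)
        assert res.contour is big

    def test_diagnostics_cover_all_candidates(self, template):
        cands = [rect_contour(400, 300), Contour(np.ones((10, 900), dtype=bool))]
        res = select_target(cands, SegmentationParams(template=template))
        assert len(res.diagnostics) == 2


class TestSegment:
    def test_clean_scene_recovers_truth(self, clean_scene, seg_params):
        scene, truth = clean_scene
        res = segment(scene, seg_params)
        assert res.success
        inter = np.logical_and(res.mask, truth).sum()
        union = np.logical_or(res.mask, truth).sum()
        assert inter / union >= 0.99

    def test_deterministic(self, clean_scene, seg_params):
        scene, _ = clean_scene
        r1 = segment(scene, seg_params)
        r2 = segment(scene, seg_params)
        np.testing.assert_array_equal(r1.mask, r2.mask)

    def test_heavy_overexposure_degrades_or_fails(self, seg_params):
        cfg = SceneConfig(overexposure_fraction=0.6)
        scene, truth = render_scene(CalfShapeParams(), cfg, seed=2)
        res = segment(scene, seg_params)
        if res.success:
            inter = np.logical_and(res.mask, truth).sum()
            union = np.logical_or(res.mask, truth).sum()
            assert inter / union < 0.9
        else:
            assert res.status is not SegmentationStatus.SUCCESS

    def test_empty_scene_yields_failure_status(self, scene_config, seg_params):
        h, w = scene_config.image_size
        depth = np.full((h, w), scene_config.camera_height_mm)
        hue = scene_config.depth_to_hue(depth)
        from skimage.color import hsv2rgb

        hsv = np.stack([hue / 179.0, np.full_like(hue, 0.9), np.full_like(hue, 0.95)], -1)
        scene = DepthScene(depth=depth, color=(hsv2rgb(hsv) * 255).astype(np.uint8))
        res = segment(scene, seg_params)
        assert res.status in (SegmentationStatus.NO_CONTOURS, SegmentationStatus.NO_MATCH)
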