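import numpy as np
import pytest

from conftest import pearson_ncc_oracle
from tearfilm.image import ChannelImage, RGBImage
from tearfilm.roi import (
    NoROIError,
    ROITemplate,
    extract_roi,
    generate_templates,
    normalised_cross_correlation,
)


def tpl_from(arr, mask=None):
    mask = np.ones(arr.shape, dtype=bool) if mask is None else mask
    return ROITemplate(arr, mask, "t")


class TestNCC:
    def test_exact_subwindow_scores_one(self, rng):
        img = rng.uniform(size=(20, 24))
        sub = img[5:12, 8:16]
        m = normalised_cross_correlation(ChannelImage(img), tpl_from(sub))
        assert m[5, 8] == pytest.approx(1.0, abs=1e-9)

    def test_negated_subwindow_scores_minus_one(self, rng):
        img = rng.uniform(size=(20, 24))
        sub = 3.0 - 2.0 * img[5:12, 8:16]  # affine inversion
        m = normalised_cross_correlation(ChannelImage(img), tpl_from(sub))
        assert m[5, 8] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.uniform(size=(16, 16))
        t = rng.uniform(size=(5, 5))
        got = normalised_cross_correlation(ChannelImage(img), tpl_from(t))
        want = pearson_ncc_oracle(img, t)
        assert got.shape == (12, 12)
        assert np.abs(got - want).max() < 1e-10

    def test_fft_path_matches_oracle_large(self, rng):
        img = rng.uniform(size=(64, 64))
        t = rng.uniform(size=(9, 11))
        got = normalised_cross_correlation(ChannelImage(img), tpl_from(t))
        want = pearson_ncc_oracle(img, t)
        assert np.abs(got - want).max() < 1e-6

    def test_affine_intensity_invariance(self, rng):
        img = rng.uniform(size=(32, 32))
        t = rng.uniform(size=(7, 7))
        tpl = tpl_from(t)
        m1 = normalised_cross_correlation(ChannelImage(img), tpl)
        m2 = normalised_cross_correlation(ChannelImage(2.5 * img + 0.7), tpl)
        assert np.abs(m1 - m2).max() < 1e-8

    def test_zero_variance_window_scores_zero(self, rng):
        img = np.zeros((12, 12))
        img[6:, 6:] = rng.uniform(size=(6, 6))
        t = rng.uniform(size=(4, 4))
        m = normalised_cross_correlation(ChannelImage(img), tpl_from(t))
        assert m[0, 0] == 0.0

    def test_template_larger_than_image_raises(self, rng):
        with pytest.raises(ValueError, match="larger than image"):
            normalised_cross_correlation(
                ChannelImage(rng.uniform(size=(8, 8))), tpl_from(rng.uniform(size=(10, 10)))
            )

    def test_scores_bounded(self, rng):
        img = rng.uniform(size=(40, 40))
        t = rng.uniform(size=(6, 6))
        m = normalised_cross_correlation(ChannelImage(img), tpl_from(t))
        assert m.min() >= -1.0 and m.max() <= 1.0


class TestTemplateGeneration:
    def test_default_set_valid(self):
        tpls = generate_templates()
        assert len(tpls) >= 4
        for t in tpls:
            assert t.weights.std() > 0
            assert t.subtemplate_mask.any()
            assert t.subtemplate_mask.shape == t.weights.shape

    def test_deterministic(self):
        a = generate_templates()
        b = generate_templates()
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.weights, y.weights)
            assert x.template_id == y.template_id

    def test_empty_config_raises(self):
        with pytest.raises(ValueError, match="empty"):
            generate_templates({})

    def test_oversized_template_errors_at_use(self, rng):
        img = RGBImage(rng.uniform(size=(40, 40, 3)))
        tpls = generate_templates({"sizes": [(64, 192)]})
        with pytest.raises(ValueError, match="exceeds image"):
            extract_roi(img, tpls)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ROITemplate(np.ones((4, 4)), np.ones((4, 4), bool), "flat")
        with pytest.raises(ValueError, match="nonempty"):
            ROITemplate(np.eye(4), np.zeros((4, 4), bool), "nomask")


class TestExtractROI:
    def test_planted_template_recovered_exactly(self):
        tpl = generate_templates()[0]
        h, w = tpl.shape
        px = np.zeros((h + 40, w + 30, 3))
        patch = 0.05 + 0.9 * tpl.weights / tpl.weights.max()
        px[17:17 + h, 9:9 + w, :] = patch[:, :, None]
        res = extract_roi(RGBImage(px), [tpl])
        assert abs(res.top_left[0] - 17) <= 1 and abs(res.top_left[1] - 9) <= 1
        assert res.score > 0.9
        r0, c0, r1, c1 = tpl.mask_bbox()
        np.testing.assert_allclose(
            res.crop.pixels, px[17 + r0:17 + r1, 9 + c0:9 + c1, :], atol=1e-12
        )

    def test_constant_image_raises(self):
        img = RGBImage(np.full((80, 120, 3), 0.4))
        with pytest.raises(NoROIError):
            extract_roi(img, generate_templates({"sizes": [(32, 96)]}))

    def test_empty_template_list_raises(self, random_rgb):
        with pytest.raises(ValueError, match="empty"):
            extract_roi(random_rgb, [])

    def test_score_is_ncc_at_top_left(self, rng):
        from tearfilm.colour import rgb_to_lab

        img = RGBImage(rng.uniform(size=(80, 100, 3)))
        tpls = generate_templates({"sizes": [(32, 96)]})
        res = extract_roi(img, tpls)
        L, _, _ = rgb_to_lab(img)
        tpl = next(t for t in tpls if t.template_id == res.template_id)
        m = normalised_cross_correlation(L, tpl)
        assert res.score == pytest.approx(float(m[res.top_left]), abs=1e-12)
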