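import numpy as np
import pytest
from scipy import ndimage

from tearfilm.colour import (
    OpponentTransformSpec,
    channels_in_space,
    descriptor_in_space,
    lab_to_rgb,
    rgb_to_lab,
    rgb_to_opponent,
    to_grayscale,
)
from tearfilm.image import RGBImage


def const_rgb(c, shape=(16, 16)):
    return RGBImage(np.full(shape + (3,), float(c)))


class TestGrayscale:
    def test_white_maps_to_one(self):
        assert np.allclose(to_grayscale(const_rgb(1.0)).pixels, 1.0)

    def test_black_maps_to_zero(self):
        assert np.allclose(to_grayscale(const_rgb(0.0)).pixels, 0.0)

    @pytest.mark.parametrize("c", [0.1, 0.25, 0.5, 0.9])
    def test_grey_axis_fixed_point(self, c):
        assert np.allclose(to_grayscale(const_rgb(c)).pixels, c)

    def test_range(self, random_rgb):
        g = to_grayscale(random_rgb).pixels
        assert g.min() >= 0 and g.max() <= 1


class TestLab:
    def test_white_point(self):
        L, a, b = rgb_to_lab(const_rgb(1.0))
        assert np.allclose(L.pixels, 100.0, atol=1e-3)
        assert np.all(np.abs(a.pixels) < 0.5)
        assert np.all(np.abs(b.pixels) < 0.5)

    def test_black(self):
        L, _, _ = rgb_to_lab(const_rgb(0.0))
        assert np.allclose(L.pixels, 0.0, atol=1e-6)

    def test_neutral_axis(self):
        _, a, b = rgb_to_lab(const_rgb(0.5))
        assert np.all(np.abs(a.pixels) < 0.5)
        assert np.all(np.abs(b.pixels) < 0.5)

    def test_round_trip_on_gamut_grid(self):
        vals = np.linspace(0.05, 0.95, 6)
        r, g, b = np.meshgrid(vals, vals, vals, indexing="ij")
        px = np.stack([r, g, b], axis=-1).reshape(6, 36, 3)
        img = RGBImage(px)
        L, a, bb = rgb_to_lab(img)
        back = lab_to_rgb(L.pixels, a.pixels, bb.pixels)
        assert np.abs(back - px).max() < 1e-6


class TestOpponent:
    def test_zero_image(self):
        rg, gr, by = rgb_to_opponent(const_rgb(0.0))
        for ch in (rg, gr, by):
            assert np.allclose(ch.pixels, 0.0)

    @pytest.mark.parametrize("c", [0.2, 0.7])
    def test_constant_image(self, c):
        rg, gr, by = rgb_to_opponent(const_rgb(c, shape=(32, 32)))
        assert np.allclose(rg.pixels, 0.0, atol=1e-12)
        assert np.allclose(gr.pixels, 0.0, atol=1e-12)
        assert np.allclose(by.pixels, -c, atol=1e-12)

    def test_delta_green_pixel_gives_negated_kernel(self):
        spec = OpponentTransformSpec(lowpass_width=1.5)
        k = spec.kernel()
        n = 41
        px = np.zeros((n, n, 3))
        px[n // 2, n // 2, 1] = 1.0
        rg, _, _ = rgb_to_opponent(RGBImage(px), spec)
        r = k.shape[0] // 2
        centre = rg.pixels[n // 2 - r:n // 2 + r + 1, n // 2 - r:n // 2 + r + 1]
        assert np.abs(centre + k).max() < 1e-12

    def test_direct_convolution_oracle(self, rng):
        spec = OpponentTransformSpec(lowpass_width=1.0)
        px = rng.uniform(size=(24, 24, 3))
        rg, gr, by = rgb_to_opponent(RGBImage(px), spec)
        k = spec.kernel()
        conv = lambda x: ndimage.convolve(x, k, mode="reflect")
        assert np.allclose(rg.pixels, px[..., 0] - conv(px[..., 1]), atol=1e-12)
        assert np.allclose(gr.pixels, px[..., 1] - conv(px[..., 0]), atol=1e-12)
        assert np.allclose(by.pixels, px[..., 2] - conv(px[..., 0] + px[..., 1]), atol=1e-12)

    def test_linearity(self, rng):
        a, b = 0.3, 0.6
        p1 = rng.uniform(size=(20, 20, 3))
        p2 = rng.uniform(size=(20, 20, 3))
        mix = rgb_to_opponent(RGBImage(a * p1 + b * p2))
        one = rgb_to_opponent(RGBImage(p1))
        two = rgb_to_opponent(RGBImage(p2))
        for m, x, y in zip(mix, one, two):
            assert np.allclose(m.pixels, a * x.pixels + b * y.pixels, atol=1e-10)

    def test_unit_dc_gain(self):
        assert abs(OpponentTransformSpec().kernel().sum() - 1.0) < 1e-12


class TestDescriptorAssembly:
    def test_cooccurrence_lengths(self, random_rgb):
        assert descriptor_in_space(random_rgb, "cooccurrence", "gray", d=1).size == 28
        assert descriptor_in_space(random_rgb, "cooccurrence", "lab", d=1).size == 84

    def test_butterworth_opponent_length(self, random_rgb):
        assert descriptor_in_space(random_rgb, "butterworth", "opponent", band=2).size == 48

    def test_concatenation_is_stable(self, random_rgb):
        d1 = descriptor_in_space(random_rgb, "wavelet", "lab")
        d2 = descriptor_in_space(random_rgb, "wavelet", "lab")
        np.testing.assert_array_equal(d1, d2)

    def test_lab_concatenation_order(self, random_rgb):
        from tearfilm.texture import wavelet_descriptor

        full = descriptor_in_space(random_rgb, "wavelet", "lab")
        L, a, b = rgb_to_lab(random_rgb)
        np.testing.assert_array_equal(full[:12], wavelet_descriptor(L))
        np.testing.assert_array_equal(full[12:24], wavelet_descriptor(a))
        np.testing.assert_array_equal(full[24:], wavelet_descriptor(b))

    def test_unknown_method_raises(self, random_rgb):
        with pytest.raises(ValueError, match="unknown texture method"):
            descriptor_in_space(random_rgb, "lbp", "gray")

    def test_unknown_space_raises(self, random_rgb):
        with pytest.raises(ValueError, match="unknown colour space"):
            descriptor_in_space(random_rgb, "wavelet", "hsv")

    def test_channels_in_space_tags(self, random_rgb):
        assert [c.space_tag for c in channels_in_space(random_rgb, "gray")] == ["gray"]
        assert [c.space_tag for c in channels_in_space(random_rgb, "lab")] == ["L", "a", "b"]
        assert [c.space_tag for c in channels_in_space(random_rgb, "opponent")] == ["RG", "GR", "BY"]
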