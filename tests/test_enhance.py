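"""Enhancement chain: definitions, oracles, invariants."""

from __future__ import annotations

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage as ndi

import _oracles as oracle
from mlcquant.core import EnFaceImage, ImageGeometry
from mlcquant.enhance import (
    PreprocessConfig,
    SEShape,
    StructuringElement,
    default_tophat_elements,
    gaussian_highpass,
    preprocess,
    rolling_ball_subtract,
    tophat_chain,
    white_top_hat,
)

ALL_SHAPES = list(SEShape)


class TestStructuringElement:
    @pytest.mark.parametrize("shape", ALL_SHAPES)
    @pytest.mark.parametrize("radius", [1, 3, 10])
    def test_offsets_symmetric_and_counted(self, shape, radius):
        se = StructuringElement(shape, radius)
        offs = se.offsets
        assert all((-dr, -dc) in offs for dr, dc in offs)
        expected = (2 * radius + 1) ** 2 if shape == SEShape.square else 2 * radius + 1
        assert len(offs) == expected

    def test_line_directions(self):
        assert StructuringElement(SEShape.line_0deg, 2).offsets == {
            (0, d) for d in range(-2, 3)
        }
        assert StructuringElement(SEShape.line_90deg, 2).offsets == {
            (d, 0) for d in range(-2, 3)
        }
        assert StructuringElement(SEShape.line_45deg, 2).offsets == {
            (-d, d) for d in range(-2, 3)
        }
        assert StructuringElement(SEShape.line_135deg, 2).offsets == {
            (d, d) for d in range(-2, 3)
        }

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(SEShape.square, 0)


class TestWhiteTopHat:
    def test_flat_image_gives_zero(self):
        img = np.full((9, 9), 37.0)
        out = white_top_hat(img, StructuringElement(SEShape.square, 2))
        assert np.array_equal(out, np.zeros((9, 9)))

    def test_isolated_peak_extracted(self):
        img = np.full((7, 7), 10.0)
        img[3, 3] = 100.0
        out = white_top_hat(img, StructuringElement(SEShape.square, 1))
        expected = np.zeros((7, 7))
        expected[3, 3] = 90.0
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("shape", ALL_SHAPES)
    def test_matches_bruteforce_oracle(self, shape, rng):
        radius = 5 if shape == SEShape.square else 10
        se = StructuringElement(shape, radius)
        for _ in range(4):
            img = rng.integers(0, 256, (16, 16)).astype(float)
            expected = oracle.white_top_hat(img, se.footprint)
            assert np.array_equal(white_top_hat(img, se), expected)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            white_top_hat(np.zeros((0, 0)), StructuringElement(SEShape.square, 1))


class TestTophatChain:
    def test_single_element_equals_white_top_hat(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(float)
        se = StructuringElement(SEShape.line_45deg, 3)
        assert np.array_equal(tophat_chain(img, [se]), white_top_hat(img, se))

    def test_flat_image_zero_after_chain(self):
        img = np.full((32, 32), 80.0)
        assert np.all(tophat_chain(img, default_tophat_elements()) == 0)

    def test_empty_element_list_rejected(self):
        with pytest.raises(ValueError):
            tophat_chain(np.ones((4, 4)), [])

    def test_peak_survives_line_removed(self):
        """A point-like cell passes the whole chain; a long horizontal streak
        is removed by the horizontal-line top-hat."""
        peak = np.zeros((41, 41))
        peak[20, 20] = 100.0
        out_peak = tophat_chain(peak, default_tophat_elements())
        assert out_peak[20, 20] == 100.0

        line = np.zeros((41, 41))
        line[20, 8:33] = 100.0  # 25 px long, longer than the 21 px line element
        out_line = tophat_chain(line, default_tophat_elements())
        assert out_line.max() < 0.2 * out_peak[20, 20]


class TestRollingBall:
    def test_flat_image_gives_zero(self):
        assert np.all(rolling_ball_subtract(np.full((15, 15), 50.0), 5) == 0)

    def test_ramp_removed_peak_survives(self):
        cols = np.arange(32, dtype=float)
        img = np.tile(0.5 * cols, (32, 1))  # gentle ramp
        img[16, 16] += 80.0
        out = rolling_ball_subtract(img, 10)
        assert out[16, 16] > 60.0
        far = out.copy()
        far[12:21, 12:21] = 0.0
        assert far.max() < 3.0

    @pytest.mark.parametrize("radius", [2, 4, 10])
    def test_matches_bruteforce_oracle(self, radius, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        assert np.allclose(
            rolling_ball_subtract(img, radius), oracle.rolling_ball_subtract(img, radius)
        )

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.ones((4, 4)), 0)


class TestGaussianHighpass:
    def test_constant_image_gives_zero(self):
        assert np.all(gaussian_highpass(np.full((20, 20), 99.0), 10.0) == 0)

    def test_single_pixel_analytic(self):
        """Peak response = peak × (1 − center kernel weight), with the center
        weight computed from the truncated sampled-Gaussian kernel."""
        sigma = 3.0
        img = np.zeros((41, 41))
        img[20, 20] = 100.0
        out = gaussian_highpass(img, sigma)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        expected = 100.0 * (1.0 - w[radius] ** 2)
        assert out[20, 20] == pytest.approx(expected, abs=1e-9)
        assert out[20, 20] > 0

    def test_removes_dc_component(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(float)
        assert gaussian_highpass(img, 10.0).mean() < img.mean()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_highpass(np.ones((4, 4)), 0.0)


@given(
    img=hnp.arrays(
        np.uint8, st.tuples(st.integers(8, 20), st.integers(8, 20)), elements=st.integers(0, 255)
    )
)
def test_stage_antiextensive_and_nonnegative(img):
    """Every enhancement stage output lies in [0, input] pointwise."""
    arr = img.astype(float)
    for out in (
        white_top_hat(arr, StructuringElement(SEShape.square, 2)),
        rolling_ball_subtract(arr, 3),
        gaussian_highpass(arr, 2.0),
    ):
        assert np.all(out >= 0.0)
        assert np.all(out <= arr + 1e-9)


def test_translation_equivariance(rng):
    """Shifting the input shifts the output identically away from borders."""
    field = rng.integers(0, 256, (64, 64)).astype(float)
    a, b = field[0:48, 0:48], field[2:50, 3:51]
    se = StructuringElement(SEShape.square, 5)
    wa, wb = white_top_hat(a, se), white_top_hat(b, se)
    assert np.array_equal(wa[14:36, 15:36], wb[12:34, 12:33])


class TestPreprocess:
    def test_flat_image_gives_zeros(self):
        geom = ImageGeometry(64, 64, 0.75, 0.75)
        img = EnFaceImage(np.full((64, 64), 120, dtype=np.uint8), geom)
        out = preprocess(img, PreprocessConfig(crop_margin_px=4))
        assert out.pixels.shape == (56, 56)
        assert np.all(out.pixels == 0)

    def test_cropped_geometry_preserves_pitch(self):
        geom = ImageGeometry(512, 512, 6.0, 6.0)
        img = EnFaceImage(np.zeros((512, 512), dtype=np.uint8), geom)
        out = preprocess(img, PreprocessConfig())
        assert out.geometry.shape == (494, 494)
        assert out.geometry.pixel_pitch_mm == pytest.approx(geom.pixel_pitch_mm)

    def test_config_roundtrip_through_yaml(self):
        cfg = PreprocessConfig(crop_margin_px=7, rolling_ball_radius=8, gaussian_sigma=5.5)
        restored = PreprocessConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
        assert restored == cfg

    def test_planted_cells_become_local_maxima(self):
        """On the default benchmark, nearly every planted cell is a local
        maximum of the enhanced image."""
        from conftest import make_benchmark_eye

        image, centers = make_benchmark_eye(seed=11)
        out = preprocess(image, PreprocessConfig())
        m = 9
        maxima = out.pixels == ndi.maximum_filter(out.pixels, size=5, mode="reflect")
        strong = maxima & (out.pixels > 10)
        hit = 0
        for r, c in centers - m:
            r0, r1 = int(r) - 2, int(r) + 3
            c0, c1 = int(c) - 2, int(c) + 3
            hit += bool(strong[r0:r1, c0:c1].any())
        assert hit / len(centers) >= 0.95
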