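"""Unsharp-mask technique: blur oracle, selection rule, metrics arithmetic."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluoroquant import (
    BlurParams,
    GreenChannelImage,
    LossMap,
    ToothMask,
    blur_metrics,
    mean_blur,
    run_blur,
    select_lesion_pixels,
    unsharp_difference,
)
from fluoroquant.mask_tools import ReferenceArea

from conftest import brute_force_mean_blur


def _full_mask(h, w):
    return ToothMask("UR1", np.ones((h, w), dtype=bool))


class TestMeanBlur:
    def test_uniform_brightness_preserved(self):
        mask = _full_mask(6, 6)
        g = GreenChannelImage(np.full((6, 6), 100.0))
        out = mean_blur(g, mask, BlurParams(blur_size_px=3))
        np.testing.assert_allclose(out.values[mask.pixels], 100.0)

    def test_single_bright_pixel_window_means(self):
        g = np.zeros((5, 5))
        g[2, 2] = 90.0
        out = mean_blur(GreenChannelImage(g), _full_mask(5, 5), BlurParams(3))
        assert out.values[1, 1] == pytest.approx(10.0)  # 90 / 9
        assert out.values[2, 2] == pytest.approx(10.0)
        assert out.values[0, 0] == pytest.approx(0.0)

    def test_mask_aware_beats_naive_at_edge(self):
        # bright 4x4 tooth occupying the left two columns over dark background
        g = np.zeros((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[:, :2] = True
        g[mask] = 200.0
        tooth = ToothMask("UR1", mask)
        aware = mean_blur(GreenChannelImage(g), tooth, BlurParams(3, mask_aware=True))
        naive = mean_blur(GreenChannelImage(g), tooth, BlurParams(3, mask_aware=False))
        assert aware.values[1, 1] > naive.values[1, 1]
        np.testing.assert_allclose(aware.values[mask], 200.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(2, 12), st.integers(2, 12),
        st.integers(1, 31), st.booleans(), st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force(self, h, w, size, mask_aware, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 255, (h, w))
        m = rng.random((h, w)) > 0.3
        m[0, 0] = True
        out = mean_blur(
            GreenChannelImage(g), ToothMask("UR1", m),
            BlurParams(size, mask_aware=mask_aware),
        )
        expected = brute_force_mean_blur(g, m, size, mask_aware)
        np.testing.assert_allclose(out.values[m], expected[m], atol=1e-9)
        assert (out.values[~m] == 0).all()


class TestUnsharpDifference:
    def test_identical_images_zero_loss(self):
        mask = _full_mask(4, 4)
        g = GreenChannelImage(np.full((4, 4), 120.0))
        loss = unsharp_difference(g, g, mask)
        assert (loss.values == 0).all()
        assert not loss.threshold_applied

    def test_dip_below_flat_blur(self):
        mask = _full_mask(3, 3)
        g = np.full((3, 3), 100.0)
        g[1, 1] = 80.0
        blurred = GreenChannelImage(np.full((3, 3), 100.0))
        loss = unsharp_difference(GreenChannelImage(g), blurred, mask)
        assert loss.values[1, 1] == pytest.approx(20.0)

    def test_brighter_than_blur_clamps_to_zero(self):
        mask = _full_mask(3, 3)
        g = np.full((3, 3), 150.0)
        blurred = GreenChannelImage(np.full((3, 3), 100.0))
        loss = unsharp_difference(GreenChannelImage(g), blurred, mask)
        assert (loss.values == 0).all()


class TestLesionSelection:
    def _reference(self, shape, rows, cols):
        pix = np.zeros(shape, dtype=bool)
        pix[np.ix_(rows, cols)] = True
        return ReferenceArea(pix, centroid=(float(cols[0]), float(rows[0])))

    def test_two_sd_rule_on_known_base_stats(self):
        shape = (4, 6)
        loss_vals = np.zeros(shape)
        loss_vals[0, :4] = [3.0, 3.0, 0.0, 0.0]  # base mean 1.5, SD 1.5
        loss_vals[1, 0] = 6.0
        loss_vals[1, 1] = 4.0
        loss = LossMap(loss_vals, threshold_applied=False, method_tag="blur")
        mask = _full_mask(*shape)
        ref = self._reference(shape, [0], [0, 1, 2, 3])
        # base mean 1.5, sd 1.5 -> threshold 4.5 at k=2
        sel = select_lesion_pixels(loss, mask, ref, BlurParams(k_sd=2.0))
        assert sel[1, 0] and not sel[1, 1]

    def test_all_zero_loss_empty_selection(self):
        shape = (3, 3)
        loss = LossMap(np.zeros(shape), threshold_applied=False, method_tag="blur")
        sel = select_lesion_pixels(
            loss, _full_mask(*shape), self._reference(shape, [0], [0, 1])
        )
        assert not sel.any()

    def test_k_zero_selects_everything_above_mean(self):
        shape = (2, 4)
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [2.0, 0.5, 1.5, 1.0]])
        loss = LossMap(vals, threshold_applied=False, method_tag="blur")
        ref = self._reference(shape, [0], [0, 1, 2, 3])  # mean 1, sd 0
        sel = select_lesion_pixels(loss, _full_mask(*shape), ref, BlurParams(k_sd=0.0))
        assert sel[1, 0] and sel[1, 2] and not sel[1, 1] and not sel[1, 3]

    def test_empty_reference_errors(self):
        shape = (2, 2)
        loss = LossMap(np.zeros(shape), threshold_applied=False, method_tag="blur")
        ref = self._reference((4, 4), [0], [0])  # wrong-shape -> empty overlap
        with pytest.raises((ValueError, IndexError)):
            select_lesion_pixels(loss, _full_mask(*shape), ref)


class TestBlurMetrics:
    def _fixture(self, n_lesion=10, loss_value=20.0, blurred_value=200.0):
        shape = (4, 5)
        loss_vals = np.zeros(shape)
        lesion = np.zeros(shape, dtype=bool)
        lesion.flat[:n_lesion] = True
        loss_vals[lesion] = loss_value
        loss = LossMap(loss_vals, threshold_applied=False, method_tag="blur")
        blurred = GreenChannelImage(np.full(shape, blurred_value))
        return loss, lesion, blurred

    def test_arithmetic_oracle(self):
        loss, lesion, blurred = self._fixture()
        m = blur_metrics(loss, lesion, blurred, mm_per_pixel=0.1)
        assert m.delta_f == pytest.approx(10.0)  # 100 * 20/200
        assert m.area == pytest.approx(0.1)  # 10 px * 0.01 mm^2
        assert m.delta_q == pytest.approx(1.0)
        assert m.area_unit == "mm2"

    def test_empty_lesion_zero_metrics(self):
        loss, _, blurred = self._fixture(n_lesion=0)
        m = blur_metrics(loss, np.zeros((4, 5), dtype=bool), blurred)
        assert (m.area, m.delta_f, m.delta_q) == (0.0, 0.0, 0.0)

    def test_doubling_loss_doubles_delta_f_and_q(self):
        loss1, lesion, blurred = self._fixture(loss_value=15.0)
        loss2 = LossMap(loss1.values * 2, threshold_applied=False, method_tag="blur")
        m1 = blur_metrics(loss1, lesion, blurred)
        m2 = blur_metrics(loss2, lesion, blurred)
        assert m2.delta_f == pytest.approx(2 * m1.delta_f)
        assert m2.delta_q == pytest.approx(2 * m1.delta_q)
        assert m2.area == m1.area

    def test_pixel_area_flagged_without_scale(self):
        loss, lesion, blurred = self._fixture()
        m = blur_metrics(loss, lesion, blurred, mm_per_pixel=None)
        assert m.area == 10 and m.area_unit == "px"

    def test_zero_blur_pixels_skipped(self):
        loss, lesion, _ = self._fixture()
        b = np.full((4, 5), 200.0)
        b[0, 0] = 0.0
        m = blur_metrics(loss, lesion, GreenChannelImage(b))
        assert m.n_skipped == 1
        assert m.delta_f == pytest.approx(10.0)


def test_shift_invariance_of_full_pipeline(rng):
    h, w = 40, 50
    mask = np.zeros((h, w), dtype=bool)
    mask[5:35, 5:25] = True
    g = np.zeros((h, w))
    g[mask] = 180.0
    g[12:20, 8:16] = 150.0  # lesion dip
    ref_pix = np.zeros((h, w), dtype=bool)
    ref_pix[28:33, 10:15] = True

    def run(shift):
        gm = np.roll(g, shift, axis=1)
        mm = np.roll(mask, shift, axis=1)
        rr = np.roll(ref_pix, shift, axis=1)
        metrics, _ = run_blur(
            GreenChannelImage(gm), ToothMask("UR1", mm),
            ReferenceArea(rr, centroid=(0.0, 0.0)), BlurParams(blur_size_px=9),
        )
        return metrics

    m0, m1 = run(0), run(7)
    assert m1.area == m0.area
    assert m1.delta_f == pytest.approx(m0.delta_f)
    assert m1.delta_q == pytest.approx(m0.delta_q)


def test_delta_q_identity_always(rng):
    for _ in range(10):
        shape = (6, 6)
        lesion = rng.random(shape) > 0.5
        loss = LossMap(
            rng.uniform(0, 30, shape) * lesion, threshold_applied=False, method_tag="blur"
        )
        blurred = GreenChannelImage(rng.uniform(50, 250, shape))
        m = blur_metrics(loss, lesion, blurred, mm_per_pixel=0.08)
        assert m.delta_q == m.delta_f * m.area
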