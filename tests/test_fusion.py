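"""NAMM fusion, color-sensitivity arithmetic and the model variants."""

import numpy as np
import pytest

from conftest import make_ycbcr
from csjnd.base_effects import ThresholdMap
from csjnd.config import ModelConfig
from csjnd.errors import ChannelMismatchError
from csjnd.fixtures import FixtureSpec
from csjnd.fusion import (
    apply_cs,
    color_sensitivity,
    compute_model,
    cs_weights,
    modulate_masking,
    namm_fuse,
    sensitivity_params,
    visual_masking,
)


def tmap(value, kind="CM", channel="Y", shape=(8, 8)):
    return ThresholdMap(np.full(shape, float(value)), kind, channel)


class TestMaskingCombination:
    def test_product_with_zero_factor(self):
        vm = visual_masking(tmap(0.0), tmap(2.0, "PM"), tmap(3.0, "EP"))
        assert np.all(vm.data == 0.0)

    def test_product_arithmetic(self):
        vm = visual_masking(tmap(3.384), tmap(0.7921, "PM"), tmap(1.17, "EP"))
        assert vm.data[0, 0] == pytest.approx(3.384 * 0.7921 * 1.17)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ChannelMismatchError):
            visual_masking(tmap(1, channel="Y"), tmap(1, "PM", channel="Cb"),
                           tmap(1, "EP", channel="Y"))

    @pytest.mark.parametrize("u, expected", [(1.0, 4.0), (0.0, 0.0), (0.75, 3.0)])
    def test_saliency_modulation_products(self, u, expected):
        vms = modulate_masking(tmap(4.0, "VM"), np.full((8, 8), u))
        assert np.all(vms.data == expected)
        assert np.all(vms.data <= 4.0)


class TestNammFusion:
    def test_no_masking_reduces_to_adaptation(self):
        fused = namm_fuse(tmap(5.0, "LA"), tmap(0.0, "VMS"))
        assert np.all(fused.data == 5.0)

    def test_direct_arithmetic(self):
        fused = namm_fuse(tmap(20.0, "LA"), tmap(10.0, "VMS"), alpha=0.3)
        assert np.all(fused.data == pytest.approx(27.0))

    def test_equal_inputs_identity(self):
        fused = namm_fuse(tmap(4.0, "LA"), tmap(4.0, "VMS"), alpha=0.3)
        assert np.all(fused.data == pytest.approx(1.7 * 4.0))

    def test_sandwich_bounds_random_maps(self, rng):
        la = rng.uniform(0, 20, (16, 16))
        vms = rng.uniform(0, 30, (16, 16))
        fused = namm_fuse(ThresholdMap(la, "LA"), ThresholdMap(vms, "VMS"), 0.3).data
        assert np.all(fused >= np.maximum(la, vms) - 1e-12)
        assert np.all(fused <= la + vms + 1e-12)

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            namm_fuse(tmap(1, "LA"), tmap(1, "VMS"), alpha=1.0)


class TestColorSensitivity:
    def test_measured_distance_ratio_reproduces_parameters(self):
        s = sensitivity_params((1.0, 0.432, 0.501))
        assert s == pytest.approx((0.695, 0.130, 0.175), abs=1e-3)
        assert sum(s) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_ratio(self):
        assert sensitivity_params((1.0, 1.0, 1.0)) == pytest.approx((1 / 3,) * 3)

    def test_weights_from_printed_parameters(self):
        w = cs_weights((0.695, 0.130, 0.175))
        assert w == pytest.approx((0.291, 1.554, 1.155), abs=1e-3)
        assert sum(w) == pytest.approx(3.0, abs=1e-12)

    def test_symmetric_weights(self):
        assert cs_weights((1 / 3, 1 / 3, 1 / 3)) == pytest.approx((1.0, 1.0, 1.0))

    def test_weight_ordering_inverse_to_sensitivity(self):
        cs = color_sensitivity()
        order_s = np.argsort(cs.s_params)
        order_w = np.argsort(cs.weights)[::-1]
        assert np.array_equal(order_s, order_w)

    def test_unrounded_propagation_differs_in_third_decimal(self):
        printed = color_sensitivity(cs_from="printed").weights
        full = color_sensitivity(cs_from="unrounded").weights
        assert printed != full
        assert printed == pytest.approx(full, abs=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sensitivity_params((1.0, -0.4, 0.5))
        with pytest.raises(ValueError):
            cs_weights((0.0, 0.5, 0.5))

    def test_apply_cs_scales_by_channel_weight(self):
        cs = color_sensitivity()
        y = apply_cs(tmap(3.0, "JND_S", "Y"), cs)
        cb = apply_cs(tmap(3.0, "JND_S", "Cb"), cs)
        assert y.data[0, 0] == pytest.approx(cs.weights[0] * 3.0)
        assert cb.data[0, 0] == pytest.approx(cs.weights[1] * 3.0)


@pytest.fixture(scope="module")
def texture():
    return make_ycbcr(FixtureSpec("random_texture", (32, 32), {"seed": 3}))


class TestModelVariants:
    def test_flat_image_closed_form(self):
        rgb, ycc = make_ycbcr(FixtureSpec("flat", (64, 64), {"level": 128}))
        res = compute_model(ycc, rgb)
        la = 3.0 * (128 - 127) / 128 + 3.0
        w = res.sensitivity.weights
        for ch, weight in zip(("Y", "Cb", "Cr"), w):
            assert np.allclose(res.maps[ch].data, weight * la, atol=1e-9)

    def test_variant_b_equals_s_on_flat_image(self):
        # a constant saliency map degenerates to U_S = 1 (identity modulation)
        rgb, ycc = make_ycbcr(FixtureSpec("flat", (32, 32), {"level": 100}))
        b = compute_model(ycc, rgb, ModelConfig(variant="B"))
        s = compute_model(ycc, rgb, ModelConfig(variant="S"))
        for ch in ("Y", "Cb", "Cr"):
            assert np.array_equal(b.maps[ch].data, s.maps[ch].data)

    def test_cs_composes_over_variants(self, texture):
        rgb, ycc = texture
        results = {v: compute_model(ycc, rgb, ModelConfig(variant=v))
                   for v in ("B", "S", "C", "full")}
        weights = color_sensitivity().weights
        for ch, w in zip(("Y", "Cb", "Cr"), weights):
            assert np.allclose(results["C"].maps[ch].data,
                               w * results["B"].maps[ch].data, atol=1e-9)
            assert np.allclose(results["full"].maps[ch].data,
                               w * results["S"].maps[ch].data, atol=1e-9)

    def test_saliency_only_reduces_thresholds(self, texture):
        rgb, ycc = texture
        b = compute_model(ycc, rgb, ModelConfig(variant="B"))
        s = compute_model(ycc, rgb, ModelConfig(variant="S"))
        for ch in ("Y", "Cb", "Cr"):
            assert np.all(s.maps[ch].data <= b.maps[ch].data + 1e-9)

    def test_saliency_disabled_equals_basic(self, texture):
        rgb, ycc = texture
        cfg = ModelConfig(variant="S")
        cfg.saliency.enabled = False
        off = compute_model(ycc, rgb, cfg)
        b = compute_model(ycc, rgb, ModelConfig(variant="B"))
        for ch in ("Y", "Cb", "Cr"):
            assert np.array_equal(off.maps[ch].data, b.maps[ch].data)

    def test_saliency_variant_requires_rgb(self, texture):
        _, ycc = texture
        with pytest.raises(ValueError, match="RGB"):
            compute_model(ycc, None, ModelConfig(variant="full"))

    def test_all_outputs_nonnegative_and_shaped(self, texture):
        rgb, ycc = texture
        res = compute_model(ycc, rgb)
        for ch in ("Y", "Cb", "Cr"):
            cm = res.channels[ch]
            for m in (cm.la, cm.cm, cm.pm, cm.ep, cm.vm, cm.vms, cm.jnd):
                assert m.data.shape == ycc.shape
                assert np.all(m.data >= 0.0)
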