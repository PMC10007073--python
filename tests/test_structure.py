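"""Orientation fields, pattern complexity and edge protection."""

import numpy as np
import pytest

from csjnd.config import StructureConfig
from csjnd.structure import (
    DIRECTIONAL_KERNELS,
    SENTINEL,
    OrientationField,
    directional_gradients,
    edge_protection,
    edge_weight,
    gradient_orientation,
    pattern_complexity,
    pattern_masking,
    quantize_orientation,
)


def horizontal_step(h=16, w=16, lo=0.0, hi=255.0):
    plane = np.full((h, w), lo)
    plane[h // 2:, :] = hi
    return plane


def brute_force_pc(quantized, n_bins, window):
    """Independent per-pixel histogram recount (reference oracle)."""
    r = window // 2
    padded = np.pad(quantized, r, mode="edge")
    out = np.zeros_like(quantized)
    for i in range(quantized.shape[0]):
        for j in range(quantized.shape[1]):
            region = padded[i:i + window, j:j + window].ravel()
            out[i, j] = len({b for b in region if b != SENTINEL})
    return out


class TestOrientation:
    def test_horizontal_step_gives_vertical_gradient(self):
        field = gradient_orientation(horizontal_step())
        band = field.magnitude_map > 1.0
        assert band.any()
        assert np.allclose(field.phi_map[band], 90.0)

    def test_vertical_step_gives_horizontal_gradient(self):
        field = gradient_orientation(horizontal_step().T)
        band = field.magnitude_map > 1.0
        assert np.allclose(np.mod(field.phi_map[band], 180.0) % 180, 0.0)

    def test_constant_plane_has_zero_magnitude(self):
        field = gradient_orientation(np.full((8, 8), 50.0))
        assert np.all(field.magnitude_map == 0.0)
        q = quantize_orientation(field, 12, 2.0)
        assert np.all(q.quantized_map == SENTINEL)

    @pytest.mark.parametrize("phi, n_bins, expected", [
        (0.0, 12, 0),
        (179.9, 12, 11),
        (15.0, 12, 1),     # interval [15, 30) at 15-degree bins
        (44.9, 4, 0),      # interval [0, 45) at 45-degree bins
    ])
    def test_bin_intervals(self, phi, n_bins, expected):
        field = OrientationField(
            phi_map=np.full((5, 5), phi),
            magnitude_map=np.full((5, 5), 100.0),
        )
        q = quantize_orientation(field, n_bins, 2.0)
        assert np.all(q.quantized_map == expected)

    def test_too_few_bins_rejected(self):
        field = gradient_orientation(horizontal_step())
        with pytest.raises(ValueError, match="n_bins"):
            quantize_orientation(field, 1)


class TestPatternComplexity:
    def test_flat_plane_has_zero_complexity(self):
        field = quantize_orientation(
            gradient_orientation(np.full((10, 10), 128.0)), 12, 2.0
        )
        pc = pattern_complexity(field, 5)
        assert np.all(pc.pc_map == 0)

    def test_single_orientation_regions(self):
        # interior of a step-edge band sees exactly one orientation
        field = quantize_orientation(
            gradient_orientation(horizontal_step(16, 16)), 12, 2.0
        )
        pc = pattern_complexity(field, 5).pc_map
        h = 16 // 2
        assert np.all(pc[h - 1: h + 1, 4:-4] == 1)
        assert np.all(pc[:2, :] == 0)  # far from the edge: no orientations

    def test_all_bins_occupied(self):
        # force every bin into one region
        n = 12
        q = np.full((9, 9), SENTINEL, dtype=np.int64)
        q[2:5, 2:6] = np.arange(12).reshape(3, 4)
        field = OrientationField(
            phi_map=np.zeros((9, 9)), magnitude_map=np.full((9, 9), 10.0),
            quantized_map=q, n_bins=n,
        )
        pc = pattern_complexity(field, 5).pc_map
        assert pc[3, 3] == n

    @pytest.mark.parametrize("n_bins", [4, 12])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_brute_force_recount(self, n_bins, seed):
        rng = np.random.default_rng(seed)
        plane = rng.integers(0, 256, size=(16, 16)).astype(float)
        field = quantize_orientation(gradient_orientation(plane), n_bins, 2.0)
        pc = pattern_complexity(field, 5).pc_map
        assert np.array_equal(pc, brute_force_pc(field.quantized_map, n_bins, 5))

    def test_even_region_rejected(self):
        field = quantize_orientation(gradient_orientation(horizontal_step()), 12, 2.0)
        with pytest.raises(ValueError, match="odd"):
            pattern_complexity(field, 4)


class TestPatternMasking:
    @pytest.mark.parametrize("pc, expected", [
        (0, 0.0),
        (1, 0.8 / 1.01),
        (12, 0.8 * 12**2.7 / (144 + 0.01)),
    ])
    def test_known_values(self, pc, expected):
        pm = pattern_masking(np.full((5, 5), pc, dtype=float))
        assert pm.data[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_over_bin_range(self):
        values = [pattern_masking(np.full((5, 5), float(k))).data[0, 0]
                  for k in range(13)]
        assert np.all(np.diff(values) > 0)


class TestEdgeStructure:
    def test_directional_kernels_are_zero_sum(self):
        for k in DIRECTIONAL_KERNELS:
            assert k.sum() == 0.0

    def test_constant_plane_zero_response(self):
        assert np.all(directional_gradients(np.full((10, 10), 99.0)) == 0.0)

    def test_offset_invariance(self, rng):
        plane = rng.uniform(0, 200, size=(12, 12))
        assert np.allclose(directional_gradients(plane),
                           directional_gradients(plane + 55.0), atol=1e-9)

    def test_step_edge_band_response(self):
        g = directional_gradients(horizontal_step(20, 20))
        assert np.all(g[9:11, 5:-5] > 0)
        assert np.allclose(g[:6, :], 0.0)   # far rows see a constant patch

    def test_edge_weight_flat_plane_is_one(self):
        w = edge_weight(np.full((16, 16), 128.0))
        assert np.allclose(w, 1.0)

    def test_edge_weight_dips_on_edge_and_recovers(self):
        w = edge_weight(horizontal_step(32, 32))
        mid = 32 // 2
        col = w[:, 16]
        assert col[mid - 1] < 0.6            # suppressed near the edge line
        assert col[2] == pytest.approx(1.0)  # recovered far away
        assert np.all((w >= 0.1) & (w <= 1.0))

    def test_edge_weight_bad_thresholds(self):
        with pytest.raises(ValueError, match="low"):
            edge_weight(horizontal_step(), low=0.5, high=0.2)

    @pytest.mark.parametrize("channel, lam", [("Y", 0.117), ("Cb", 0.65), ("Cr", 0.45)])
    def test_edge_protection_gains(self, channel, lam):
        g = np.full((8, 8), 10.0)
        w = np.ones((8, 8))
        ep = edge_protection(g, w, channel)
        assert np.allclose(ep.data, lam * 10.0)

    def test_edge_protection_zero_gradient(self):
        ep = edge_protection(np.zeros((8, 8)), np.ones((8, 8)), "Y")
        assert np.all(ep.data == 0.0)

    def test_edge_protection_unknown_channel(self):
        with pytest.raises(ValueError, match="channel"):
            edge_protection(np.zeros((8, 8)), np.ones((8, 8)), "Lab")

    def test_edges_protected_relative_to_equal_gradient(self):
        # at equal G, a pixel on the detected edge gets lower EP than one off it
        plane = horizontal_step(32, 32)
        g = directional_gradients(plane)
        w = edge_weight(plane)
        ep = edge_protection(g, w, "Y", StructureConfig()).data
        mid = 32 // 2
        on_edge = ep[mid, 16] / max(g[mid, 16], 1e-12)
        off_edge = ep[4, 16] / max(g[4, 16], 1e-12) if g[4, 16] > 0 else None
        assert w[mid, 16] < 1.0
        if off_edge is not None:
            assert on_edge < off_edge
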