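"""Fusion of the visibility effects into per-channel JND maps.

The three masking factors (contrast, pattern, edge protection) combine
multiplicatively into the visual masking estimate VM; saliency modulates
it (VM^S = VM * U_S); the nonlinear additivity model for masking (NAMM)
fuses luminance adaptation with the masking estimate,

    JND = LA + VM^S - alpha * min(LA, VM^S),

discounting their overlap with gain-reduction factor alpha; and the
color-sensitivity weights CS_theta rescale the Y/Cb/Cr sub-thresholds so
that the channel the eye scrutinises most (Y) receives the smallest
threshold.  Four model variants are exposed: "B" (no saliency, no color
weighting), "S" (saliency only), "C" (color weighting only) and "full".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_effects import (
    ThresholdMap,
    contrast_masking,
    local_contrast,
    local_mean,
    luminance_adaptation,
)
from .config import ModelConfig
from .errors import ChannelMismatchError, ShapeMismatchError
from .image_io import RGBImage, YCbCrImage
from .saliency import SaliencyMap, compute_saliency
from .structure import (
    directional_gradients,
    edge_protection,
    edge_weight,
    gradient_orientation,
    pattern_complexity,
    pattern_masking,
    quantize_orientation,
)

__all__ = [
    "ColorSensitivity",
    "ChannelMaps",
    "ModelResult",
    "visual_masking",
    "modulate_masking",
    "namm_fuse",
    "sensitivity_params",
    "cs_weights",
    "color_sensitivity",
    "apply_cs",
    "compute_model",
]

CHANNELS = ("Y", "Cb", "Cr")

#: Published three-decimal sensitivity parameters for the default
#: critical-distance ratio (1, 0.432, 0.501).  Note the published Y entry
#: (0.695) is a truncation of the computed 0.6956 while the Cb entry
#: (0.130) is a rounding of 0.12981; the triple is therefore kept as a
#: constant rather than re-derived by any single rounding rule.
PRINTED_S_PARAMS = (0.695, 0.130, 0.175)


@dataclass
class ColorSensitivity:
    """Critical-distance ratio, sensitivity parameters and CS weights.

    ``s_params`` are the per-channel shares of a perceptual unit area
    (sum 1); ``weights`` are their normalised reciprocals (sum 3), so
    the most sensitive channel gets the smallest weight.
    """

    d_ratio: tuple[float, float, float]
    s_params: tuple[float, float, float]
    weights: tuple[float, float, float]

    def weight_for(self, channel: str) -> float:
        try:
            return dict(zip(CHANNELS, self.weights))[channel]
        except KeyError:
            raise ChannelMismatchError(f"unknown channel {channel!r}") from None


def visual_masking(cm: ThresholdMap, pm: ThresholdMap,
                   ep: ThresholdMap) -> ThresholdMap:
    """VM = CM * PM * EP, pixel-wise; the three effects reinforce."""
    if not (cm.channel_label == pm.channel_label == ep.channel_label):
        raise ChannelMismatchError(
            f"channel labels disagree: {cm.channel_label}, "
            f"{pm.channel_label}, {ep.channel_label}"
        )
    if not (cm.shape == pm.shape == ep.shape):
        raise ShapeMismatchError(
            f"shapes disagree: {cm.shape}, {pm.shape}, {ep.shape}"
        )
    return ThresholdMap(cm.data * pm.data * ep.data, "VM", cm.channel_label)


def modulate_masking(vm: ThresholdMap, u_s: np.ndarray) -> ThresholdMap:
    """VM^S = VM * U_S; saliency can only reduce the masking estimate."""
    u = np.asarray(u_s, dtype=np.float64)
    if vm.shape != u.shape:
        raise ShapeMismatchError(f"shape mismatch: VM {vm.shape} vs U_S {u.shape}")
    return ThresholdMap(vm.data * u, "VMS", vm.channel_label)


def namm_fuse(la: ThresholdMap, vms: ThresholdMap,
              alpha: float = 0.3) -> ThresholdMap:
    """Nonlinear additivity fusion JND = LA + VMS - alpha min(LA, VMS).

    For alpha in [0, 1) the result is sandwiched between
    max(LA, VMS) and LA + VMS pixel-wise.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if la.shape != vms.shape:
        raise ShapeMismatchError(f"shape mismatch: LA {la.shape} vs VMS {vms.shape}")
    fused = la.data + vms.data - alpha * np.minimum(la.data, vms.data)
    return ThresholdMap(fused, "JND_S", vms.channel_label)


def sensitivity_params(
    d_ratio: tuple[float, float, float] = (1.0, 0.432, 0.501),
) -> tuple[float, float, float]:
    """Perceptual sensitivity parameters from the critical-distance ratio.

    Each channel is viewed as a perceptual sub-unit whose share of a
    unit area scales with D_theta^2:

        S_theta = D_theta^2 / (D_Y^2 + D_Cb^2 + D_Cr^2)

    With the measured ratio 1 : 0.432 : 0.501 this gives approximately
    (0.695, 0.130, 0.175): the eye resolves Y detail from much farther
    away than chroma detail, so Y dominates the perceptual area.
    """
    d = np.asarray(d_ratio, dtype=np.float64)
    if d.shape != (3,) or np.any(d <= 0):
        raise ValueError(f"d_ratio must be three positive numbers, got {d_ratio}")
    shares = d ** 2 / np.sum(d ** 2)
    return tuple(float(v) for v in shares)


def cs_weights(
    s_params: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Color-sensitivity weights: normalised reciprocal sensitivities.

    S'_theta = 1 / S_theta, then CS_theta = 3 S'_theta / sum(S').  The
    weights sum to 3 and order inversely to the sensitivities, steering
    distortion away from the channel the eye sees best.
    """
    s = np.asarray(s_params, dtype=np.float64)
    if s.shape != (3,) or np.any(s <= 0) or np.any(s >= 1):
        raise ValueError(f"s_params must be three values in (0, 1), got {s_params}")
    inv = 1.0 / s
    w = 3.0 * inv / np.sum(inv)
    return tuple(float(v) for v in w)


def color_sensitivity(d_ratio: tuple[float, float, float] = (1.0, 0.432, 0.501),
                      cs_from: str = "printed") -> ColorSensitivity:
    """Derive the full color-sensitivity triple set from the distance ratio.

    ``cs_from="printed"`` (default) derives the weights from the
    three-decimal sensitivity parameters — for the default distance
    ratio these are :data:`PRINTED_S_PARAMS`, reproducing the published
    weights (0.291, 1.554, 1.155) at that precision — while
    ``"unrounded"`` propagates full precision (0.290, 1.557, 1.153).
    """
    if cs_from not in {"printed", "unrounded"}:
        raise ValueError(f"cs_from must be 'printed' or 'unrounded', got {cs_from!r}")
    s = sensitivity_params(d_ratio)
    if cs_from == "printed":
        if tuple(d_ratio) == (1.0, 0.432, 0.501):
            basis = PRINTED_S_PARAMS
        else:
            basis = tuple(round(v, 3) for v in s)
    else:
        basis = s
    return ColorSensitivity(d_ratio=tuple(d_ratio), s_params=s,
                            weights=cs_weights(basis))


def apply_cs(jnd: ThresholdMap, sensitivity: ColorSensitivity) -> ThresholdMap:
    """Scale a channel's JND map by its color-sensitivity weight."""
    weight = sensitivity.weight_for(jnd.channel_label)
    return ThresholdMap(weight * jnd.data, "CSJND", jnd.channel_label)


@dataclass
class ChannelMaps:
    """All intermediate and final maps for one channel."""

    channel: str
    la: ThresholdMap
    cm: ThresholdMap
    pm: ThresholdMap
    ep: ThresholdMap
    vm: ThresholdMap
    vms: ThresholdMap
    jnd: ThresholdMap


@dataclass
class ModelResult:
    """Per-channel JND maps plus the shared saliency and weights."""

    variant: str
    channels: dict[str, ChannelMaps]
    saliency: SaliencyMap | None
    sensitivity: ColorSensitivity | None

    @property
    def maps(self) -> dict[str, ThresholdMap]:
        """The final threshold map of each channel."""
        return {ch: cm.jnd for ch, cm in self.channels.items()}

    def stack(self) -> np.ndarray:
        """(3, H, W) array of the final maps in Y, Cb, Cr order."""
        return np.stack([self.channels[ch].jnd.data for ch in CHANNELS])


def compute_model(img: YCbCrImage, rgb: RGBImage | None = None,
                  config: ModelConfig | None = None) -> ModelResult:
    """Run the full JND pipeline on one image.

    ``rgb`` is required when the configured variant uses saliency
    (variants "S" and "full"), because the saliency priors are defined
    on the RGB/L*a*b* image.  Luminance adaptation is computed from the
    Y plane and shared by all channels unless ``la_source`` says
    otherwise.
    """
    cfg = config or ModelConfig()
    use_saliency = cfg.variant in {"S", "full"} and cfg.saliency.enabled
    use_cs = cfg.variant in {"C", "full"}

    sal: SaliencyMap | None = None
    if cfg.variant in {"S", "full"}:
        if cfg.saliency.enabled:
            if rgb is None:
                raise ValueError(
                    f"variant {cfg.variant!r} requires the RGB image for saliency"
                )
            sal = compute_saliency(rgb, cfg.saliency)
            u_s = sal.u_map
        else:
            u_s = np.ones(img.shape)
    else:
        u_s = np.ones(img.shape)

    sens = color_sensitivity(cfg.color.d_ratio, cfg.color.cs_from)

    la_shared: ThresholdMap | None = None
    if cfg.la_source == "luma":
        mean_y = local_mean(img.y, cfg.base.window, weighted=cfg.base.weighted_mean)
        la_shared = luminance_adaptation(mean_y)

    luma_plane = img.y
    channels: dict[str, ChannelMaps] = {}
    for ch in CHANNELS:
        plane = img.plane(ch)
        if la_shared is not None:
            la = la_shared
        else:
            la = luminance_adaptation(
                local_mean(plane, cfg.base.window, weighted=cfg.base.weighted_mean)
            )

        c = local_contrast(plane, cfg.base.window, stat=cfg.base.contrast_stat)
        cm = contrast_masking(c, cfg.base.a1, cfg.base.a2, channel=ch)

        field = gradient_orientation(plane)
        field = quantize_orientation(field, cfg.structure.n_bins,
                                     cfg.structure.mag_threshold)
        pc = pattern_complexity(field, cfg.structure.region_window)
        pm = pattern_masking(pc, cfg.structure.b1, cfg.structure.b2,
                             cfg.structure.b3, channel=ch)

        edge_plane = plane if cfg.structure.edge_source == "per_channel" else luma_plane
        g = directional_gradients(edge_plane)
        w = edge_weight(edge_plane, cfg.structure.canny_sigma,
                        cfg.structure.canny_low, cfg.structure.canny_high,
                        cfg.structure.smooth_window, cfg.structure.smooth_sigma,
                        cfg.structure.edge_value)
        ep = edge_protection(g, w, ch, cfg.structure)

        vm = visual_masking(cm, pm, ep)
        vms = modulate_masking(vm, u_s) if use_saliency else ThresholdMap(
            vm.data.copy(), "VMS", ch)
        jnd = namm_fuse(la, vms, cfg.alpha)
        if use_cs:
            jnd = apply_cs(jnd, sens)
        jnd.kind_label = {"B": "JND_B", "S": "JND_S",
                          "C": "JND_C", "full": "CSJND"}[cfg.variant]
        channels[ch] = ChannelMaps(channel=ch, la=la, cm=cm, pm=pm, ep=ep,
                                   vm=vm, vms=vms, jnd=jnd)

    return ModelResult(
        variant=cfg.variant,
        channels=channels,
        saliency=sal,
        sensitivity=sens if use_cs else None,
    )
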