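"""Pattern masking and edge protection.

Pattern masking rests on the observation that distortion hides well in
regions whose local gradient orientations are diverse.  Orientation is
the angle of the Prewitt gradient folded into [0, 180) degrees (a line
and its reverse are the same orientation); each pixel's orientation is
quantised into one of ``n_bins`` bins, a histogram is collected over a
small region, and the pattern complexity PC(x) is the number of occupied
bins (the L0 norm of the histogram).  Pixels whose gradient magnitude is
at or below ``mag_threshold`` have no meaningful orientation and are
excluded, so a flat region has PC = 0 and hence no pattern masking.

Edge protection works against masking: the visual system scrutinises
edges, so thresholds near detected (Canny) edges are deliberately pulled
down by a smoothed edge weight W(x) in [edge_value, 1], scaled by the
maximal directional-gradient response G(x) and a per-channel gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .base_effects import ThresholdMap, _as_array
from .config import StructureConfig

__all__ = [
    "SENTINEL",
    "OrientationField",
    "PatternComplexityMap",
    "EdgeStructure",
    "gradient_orientation",
    "quantize_orientation",
    "pattern_complexity",
    "pattern_masking",
    "directional_gradients",
    "edge_weight",
    "edge_protection",
]

#: Bin index assigned to pixels with sub-threshold gradient magnitude.
SENTINEL = -1

# Prewitt kernels: g_v responds to horizontal edges (vertical gradient),
# g_h to vertical edges.  Row index grows downward.
_PREWITT_V = np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], dtype=np.float64)
_PREWITT_H = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64)

# The classical 5x5 directional kernel bank (0, 45, 90, 135 degrees) used
# for the maximal weighted-average gradient G(x); each response is
# normalised by 1/16.
G1 = np.array(
    [
        [0, 0, 0, 0, 0],
        [1, 3, 8, 3, 1],
        [0, 0, 0, 0, 0],
        [-1, -3, -8, -3, -1],
        [0, 0, 0, 0, 0],
    ],
    dtype=np.float64,
)
G2 = np.array(
    [
        [0, 0, 1, 0, 0],
        [0, 8, 3, 0, 0],
        [1, 3, 0, -3, -1],
        [0, 0, -3, -8, 0],
        [0, 0, -1, 0, 0],
    ],
    dtype=np.float64,
)
G3 = np.array(
    [
        [0, 0, 1, 0, 0],
        [0, 0, 3, 8, 0],
        [-1, -3, 0, 3, 1],
        [0, -8, -3, 0, 0],
        [0, 0, -1, 0, 0],
    ],
    dtype=np.float64,
)
G4 = np.array(
    [
        [0, 1, 0, -1, 0],
        [0, 3, 0, -3, 0],
        [0, 8, 0, -8, 0],
        [0, 3, 0, -3, 0],
        [0, 1, 0, -1, 0],
    ],
    dtype=np.float64,
)
DIRECTIONAL_KERNELS = (G1, G2, G3, G4)


@dataclass
class OrientationField:
    """Gradient orientation phi in [0, 180) degrees plus magnitude.

    ``quantized_map`` is filled by :func:`quantize_orientation`: bin
    indices in {0..n_bins-1}, or :data:`SENTINEL` where the magnitude is
    sub-threshold.
    """

    phi_map: np.ndarray
    magnitude_map: np.ndarray
    quantized_map: np.ndarray | None = None
    n_bins: int | None = None


@dataclass
class PatternComplexityMap:
    """Number of occupied orientation bins in each pixel's region."""

    pc_map: np.ndarray
    n_bins: int
    region_window: int


@dataclass
class EdgeStructure:
    """Directional-gradient magnitude and edge-related weight."""

    g_map: np.ndarray
    w_map: np.ndarray
    lambda_theta: float


def gradient_orientation(plane) -> OrientationField:
    """Prewitt gradient orientation and magnitude.

    phi is the angle of (g_v, g_h) folded into [0, 180): a horizontal
    step edge (rows change) gives phi = 90, a vertical step edge gives
    phi = 0.  Magnitude is the Euclidean norm of the two raw Prewitt
    responses (edge-replicate borders).
    """
    data = _as_array(plane)
    gv = ndimage.convolve(data, _PREWITT_V, mode="nearest")
    gh = ndimage.convolve(data, _PREWITT_H, mode="nearest")
    phi = np.mod(np.degrees(np.arctan2(gv, gh)), 180.0)
    mag = np.hypot(gv, gh)
    return OrientationField(phi_map=phi, magnitude_map=mag)


def quantize_orientation(field: OrientationField, n_bins: int = 12,
                         mag_threshold: float = 2.0) -> OrientationField:
    """Quantise phi into ``n_bins`` equal bins over [0, 180).

    Bin k covers [k*180/n_bins, (k+1)*180/n_bins).  Pixels with
    magnitude <= ``mag_threshold`` get :data:`SENTINEL` and never enter
    orientation histograms.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    width = 180.0 / n_bins
    q = np.floor(field.phi_map / width).astype(np.int64)
    np.clip(q, 0, n_bins - 1, out=q)
    q[field.magnitude_map <= mag_threshold] = SENTINEL
    return OrientationField(
        phi_map=field.phi_map,
        magnitude_map=field.magnitude_map,
        quantized_map=q,
        n_bins=n_bins,
    )


def pattern_complexity(field: OrientationField,
                       region_window: int = 5) -> PatternComplexityMap:
    """Count occupied orientation bins in each pixel's region.

    The region R(x) is an odd, centred ``region_window`` square with
    edge-replicate borders; PC(x) is the number of bins with at least
    one above-threshold pixel, so 0 <= PC <= n_bins.
    """
    if field.quantized_map is None or field.n_bins is None:
        raise ValueError("orientation field has not been quantized")
    if region_window < 1 or region_window % 2 == 0:
        raise ValueError(f"region_window must be odd, got {region_window}")
    q = field.quantized_map
    pc = np.zeros(q.shape, dtype=np.int64)
    for b in range(field.n_bins):
        indicator = (q == b).astype(np.float64)
        count = ndimage.uniform_filter(indicator, size=region_window,
                                       mode="nearest")
        pc += count > 0.5 / (region_window * region_window)
    return PatternComplexityMap(pc_map=pc, n_bins=field.n_bins,
                                region_window=region_window)


def pattern_masking(pc: PatternComplexityMap | np.ndarray, b1: float = 0.8,
                    b2: float = 2.7, b3: float = 0.1,
                    channel: str = "Y") -> ThresholdMap:
    """Pattern-masking threshold PM(x) = b1 PC^b2 / (PC^2 + b3^2).

    PM(0) = 0 and PM is strictly increasing in PC (b2 > 2), so complex
    regions mask more; b3 keeps the expression finite at PC = 0.
    """
    pc_map = pc.pc_map if isinstance(pc, PatternComplexityMap) else np.asarray(pc)
    pc_map = pc_map.astype(np.float64)
    if pc_map.min() < 0:
        raise ValueError("pattern complexity must be >= 0")
    pm = b1 * np.power(pc_map, b2) / (pc_map * pc_map + b3 * b3)
    return ThresholdMap(pm, "PM", channel)


def directional_gradients(plane) -> np.ndarray:
    """Maximal absolute response of the four 5x5 directional kernels.

    Each kernel is zero-sum (the response is invariant to adding a
    constant) and normalised by 1/16 so the response is a weighted
    average of gray-level differences.
    """
    data = _as_array(plane)
    responses = [
        np.abs(ndimage.convolve(data, k, mode="nearest")) / 16.0
        for k in DIRECTIONAL_KERNELS
    ]
    return np.maximum.reduce(responses)


def edge_weight(plane, canny_sigma: float = 1.4, low: float = 0.1,
                high: float = 0.3, smooth_window: int = 7,
                smooth_sigma: float = 0.8,
                edge_value: float = 0.1) -> np.ndarray:
    """Edge-related weight W(x) in [edge_value, 1].

    Canny edges (hysteresis thresholds on normalised magnitude) receive
    ``edge_value``; everything else starts at 1; the binary weight image
    is then smoothed with an odd Gaussian window so protection decays
    with distance from the edge line.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd, got {smooth_window}")
    data = _as_array(plane)
    edges = feature.canny(data / 255.0, sigma=canny_sigma,
                          low_threshold=low, high_threshold=high)
    w = np.where(edges, edge_value, 1.0)
    w = ndimage.gaussian_filter(w, sigma=smooth_sigma, mode="nearest",
                                radius=smooth_window // 2)
    return np.clip(w, edge_value, 1.0)


def edge_protection(g_map: np.ndarray, w_map: np.ndarray, channel: str,
                    config: StructureConfig | None = None) -> ThresholdMap:
    """EP(x) = lambda_theta G(x) W(x) with per-channel gain lambda.

    lambda is 0.117 / 0.65 / 0.45 for Y / Cb / Cr by default: chroma
    planes get weaker edge suppression because chroma edges are less
    scrutinised.
    """
    cfg = config or StructureConfig()
    lam = cfg.lambda_for(channel)
    g = np.asarray(g_map, dtype=np.float64)
    w = np.asarray(w_map, dtype=np.float64)
    if g.shape != w.shape:
        raise ValueError(f"shape mismatch: G {g.shape} vs W {w.shape}")
    return ThresholdMap(lam * g * w, "EP", channel)
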