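"""Luminance adaptation and contrast masking.

Both effects are driven by local first- and second-order statistics of a
single channel: the mean intensity of a small neighbourhood sets the
background-luminance adaptation threshold, and the intensity spread of
the same neighbourhood feeds a compressive transducer that models
contrast masking.  Borders are handled by edge-replicate padding so a
uniform image stays exactly uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import PlaneImage

__all__ = [
    "ThresholdMap",
    "LocalStats",
    "local_mean",
    "local_contrast",
    "local_stats",
    "luminance_adaptation",
    "contrast_masking",
]

_KINDS = {"LA", "CM", "PM", "EP", "VM", "VMS", "JND_B", "JND_S", "JND_C", "CSJND"}


@dataclass
class ThresholdMap:
    """Per-pixel non-negative visibility threshold for one channel.

    ``kind_label`` names the stage that produced the map (LA, CM, PM, EP,
    VM, VMS, or one of the fused JND kinds); ``channel_label`` is Y, Cb
    or Cr.  Values are gray levels.
    """

    data: np.ndarray
    kind_label: str
    channel_label: str = "Y"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"threshold map must be 2-D, got {self.data.shape}")
        if self.kind_label not in _KINDS:
            raise ValueError(f"unknown kind label {self.kind_label!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("threshold map contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("threshold map contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class LocalStats:
    """Local mean and spread of a plane over an odd, centred window."""

    mean_map: np.ndarray
    deviation_map: np.ndarray
    window: int


def _as_array(plane) -> np.ndarray:
    return np.asarray(getattr(plane, "data", plane), dtype=np.float64)


def _check_window(window: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")


def local_mean(plane: PlaneImage | np.ndarray, window: int = 5,
               weighted: bool = False) -> np.ndarray:
    """Mean intensity over a centred ``window`` x ``window`` neighbourhood.

    ``weighted=True`` uses a Gaussian kernel (sigma = window/4) instead
    of the default unweighted mean; borders replicate the edge row/col.
    """
    _check_window(window)
    data = _as_array(plane)
    if weighted:
        return ndimage.gaussian_filter(
            data, sigma=window / 4.0, mode="nearest", radius=window // 2
        )
    return ndimage.uniform_filter(data, size=window, mode="nearest")


def local_contrast(plane: PlaneImage | np.ndarray, window: int = 5,
                   stat: str = "std") -> np.ndarray:
    """Local contrast variation c(x) over the window.

    ``stat="std"`` (default) returns the population standard deviation,
    ``stat="var"`` the population variance.  The default is std: the
    transducer's half-saturation constant (a2 = 26) is on a gray-level
    scale, which only a deviation-scaled c can reach in natural images.
    """
    _check_window(window)
    if stat not in {"std", "var"}:
        raise ValueError(f"stat must be 'std' or 'var', got {stat!r}")
    data = _as_array(plane)
    mean = ndimage.uniform_filter(data, size=window, mode="nearest")
    mean_sq = ndimage.uniform_filter(data * data, size=window, mode="nearest")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return var if stat == "var" else np.sqrt(var)


def local_stats(plane: PlaneImage | np.ndarray, window: int = 5,
                weighted_mean: bool = False, stat: str = "std") -> LocalStats:
    """Convenience bundle of :func:`local_mean` and :func:`local_contrast`."""
    return LocalStats(
        mean_map=local_mean(plane, window, weighted=weighted_mean),
        deviation_map=local_contrast(plane, window, stat=stat),
        window=window,
    )


def luminance_adaptation(mean_map: np.ndarray) -> ThresholdMap:
    """Visibility threshold due to background luminance.

    LA(x) = 17 (1 - sqrt(l/127)) + 3         for l <= 127
    LA(x) = 3 (l - 127) / 128 + 3            for l  > 127

    High in the dark (20 at l = 0), minimal at mid-gray (3 at l = 127),
    rising gently toward white (6 at l = 255).  Continuous at l = 127.
    """
    l = np.asarray(mean_map, dtype=np.float64)
    if l.min() < -1e-9 or l.max() > 255 + 1e-9:
        raise ValueError(
            f"background luminance outside [0, 255]: "
            f"min={l.min():.3f}, max={l.max():.3f}"
        )
    l = np.clip(l, 0.0, 255.0)
    dark = 17.0 * (1.0 - np.sqrt(l / 127.0)) + 3.0
    bright = 3.0 * (l - 127.0) / 128.0 + 3.0
    return ThresholdMap(np.where(l <= 127.0, dark, bright), "LA")


def contrast_masking(c_map: np.ndarray, a1: float = 16.0, a2: float = 26.0,
                     channel: str = "Y") -> ThresholdMap:
    """Compressive contrast-masking transducer.

    CM(x) = 0.115 a1 c^2.4 / (c^2 + a2^2), with CM(0) = 0.  Strictly
    increasing in c, sublinear for large c (doubling c multiplies CM by
    2^0.4 in the limit).
    """
    c = np.asarray(c_map, dtype=np.float64)
    if c.min() < 0:
        raise ValueError("contrast map contains negative values")
    cm = 0.115 * a1 * np.power(c, 2.4) / (c * c + a2 * a2)
    return ThresholdMap(cm, "CM", channel)
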