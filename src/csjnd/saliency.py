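"""SDSP-style visual saliency and the masking modulation factor.

Saliency is estimated as the pixel-wise product of three priors
computed in CIE L*a*b* space at a reduced working resolution:

* a frequency prior S_F — salient objects live in a band of spatial
  frequencies, extracted with a log-Gabor band-pass filter whose DC
  response is zero;
* a location prior S_D — attention is biased toward the image centre,
  modelled as an isotropic Gaussian;
* a color prior S_C — warm, saturated colors attract attention,
  modelled on min-max-normalised a*/b* chroma.

The raw product S is min-max normalised to S' in [0, 1] and the
modulation factor is U_S = 1 - S': strongly salient regions are
scrutinised, so their masking estimate is suppressed.  Saliency is
computed once from the RGB image and shared by all three channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, transform

from .config import SaliencyConfig
from .image_io import RGBImage

__all__ = [
    "SaliencyMap",
    "frequency_prior",
    "location_prior",
    "color_prior",
    "combine_saliency",
    "normalize_saliency",
    "saliency_modulation",
    "compute_saliency",
]


@dataclass
class SaliencyMap:
    """Raw saliency S, normalised S' in [0, 1], and modulation U_S = 1 - S'."""

    s_map: np.ndarray
    s_norm: np.ndarray
    u_map: np.ndarray
    sf: np.ndarray | None = None
    sd: np.ndarray | None = None
    sc: np.ndarray | None = None


def _to_lab(rgb_arr: np.ndarray) -> np.ndarray:
    """(H, W, 3) floats on [0, 255] -> CIE L*a*b*."""
    return color.rgb2lab(np.clip(rgb_arr, 0.0, 255.0) / 255.0)


def _log_gabor_transfer(shape: tuple[int, int], omega0: float,
                        sigma_f: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        lg = np.exp(-(np.log(np.maximum(rho, 1e-30) / omega0)) ** 2
                    / (2.0 * sigma_f ** 2))
    lg[rho == 0] = 0.0  # kill DC: a constant image has zero band-pass energy
    return lg


def frequency_prior(rgb: RGBImage | np.ndarray, omega0: float = 0.002,
                    sigma_f: float = 6.2) -> np.ndarray:
    """Band-pass (log-Gabor) energy of the L*a*b* channels, max-normalised.

    Each of L, a, b is filtered in the frequency domain; S_F is the
    Euclidean norm of the three filtered responses scaled to [0, 1].
    A constant-color image yields S_F = 0 everywhere.
    """
    if omega0 <= 0 or sigma_f <= 0:
        raise ValueError("omega0 and sigma_f must be positive")
    arr = rgb.stack() if isinstance(rgb, RGBImage) else np.asarray(rgb, float)
    lab = _to_lab(arr)
    lg = _log_gabor_transfer(lab.shape[:2], omega0, sigma_f)
    energy = np.zeros(lab.shape[:2])
    for ch in range(3):
        filtered = np.real(np.fft.ifft2(np.fft.fft2(lab[..., ch]) * lg))
        energy += filtered * filtered
    sf = np.sqrt(energy)
    peak = sf.max()
    return sf / peak if peak > 0 else sf


def location_prior(height: int, width: int, sigma_d: float = 114.0) -> np.ndarray:
    """Centre-bias Gaussian S_D(x) = exp(-||x - c||^2 / sigma_d^2)."""
    if sigma_d <= 0:
        raise ValueError("sigma_d must be positive")
    cy = (height - 1) / 2.0
    cx = (width - 1) / 2.0
    yy = (np.arange(height)[:, None] - cy) ** 2
    xx = (np.arange(width)[None, :] - cx) ** 2
    return np.exp(-(yy + xx) / sigma_d ** 2)


def color_prior(rgb: RGBImage | np.ndarray, sigma_c: float = 0.25) -> np.ndarray:
    """Warm-color prior on min-max-normalised a*/b* chroma.

    S_C = 1 - exp(-(a_n^2 + b_n^2) / sigma_c^2).  An image with constant
    chroma (e.g. pure grayscale) has no color contrast: a_n = b_n = 0
    is defined there, giving S_C = 0.
    """
    arr = rgb.stack() if isinstance(rgb, RGBImage) else np.asarray(rgb, float)
    lab = _to_lab(arr)

    def _minmax(ch: np.ndarray) -> np.ndarray:
        lo, hi = ch.min(), ch.max()
        if hi - lo < 1e-12:
            return np.zeros_like(ch)
        return (ch - lo) / (hi - lo)

    an = _minmax(lab[..., 1])
    bn = _minmax(lab[..., 2])
    return 1.0 - np.exp(-(an * an + bn * bn) / sigma_c ** 2)


def combine_saliency(sf: np.ndarray, sd: np.ndarray,
                     sc: np.ndarray) -> np.ndarray:
    """Pixel-wise product S = S_F * S_D * S_C."""
    if not (sf.shape == sd.shape == sc.shape):
        raise ValueError(
            f"prior shapes disagree: {sf.shape}, {sd.shape}, {sc.shape}"
        )
    return sf * sd * sc


def normalize_saliency(s: np.ndarray) -> np.ndarray:
    """Min-max normalise S to [0, 1]; a constant map normalises to 0.

    The degenerate rule means an image with no distinguished region
    receives U_S = 1 everywhere, i.e. unmodulated masking.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("saliency map contains non-finite values")
    lo, hi = s.min(), s.max()
    if hi - lo < 1e-12:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


def saliency_modulation(s_norm: np.ndarray) -> np.ndarray:
    """Modulation factor U_S = 1 - S'."""
    s_norm = np.asarray(s_norm, dtype=np.float64)
    if s_norm.min() < -1e-9 or s_norm.max() > 1 + 1e-9:
        raise ValueError("normalised saliency must lie in [0, 1]")
    return 1.0 - np.clip(s_norm, 0.0, 1.0)


def compute_saliency(rgb: RGBImage, config: SaliencyConfig | None = None) -> SaliencyMap:
    """Full saliency pipeline at the working resolution.

    The image is resized (bilinear) so its longer side equals
    ``working_size`` — the location-prior spread sigma_d is calibrated
    at that scale — the three priors are combined there, and the product
    is resized back to the source geometry before normalisation.
    """
    cfg = config or SaliencyConfig()
    arr = rgb.stack()
    h, w = arr.shape[:2]
    longer = max(h, w)
    if longer != cfg.working_size:
        scale = cfg.working_size / longer
        work_shape = (max(round(h * scale), 8), max(round(w * scale), 8))
        work = transform.resize(arr, work_shape, order=1, mode="edge",
                                anti_aliasing=False, preserve_range=True)
    else:
        work = arr

    sf = frequency_prior(work, cfg.omega0, cfg.sigma_f)
    sd = location_prior(work.shape[0], work.shape[1], cfg.sigma_d)
    sc = color_prior(work, cfg.sigma_c)
    s_work = combine_saliency(sf, sd, sc)

    if s_work.shape != (h, w):
        s = transform.resize(s_work, (h, w), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    else:
        s = s_work
    s = np.clip(s, 0.0, None)
    s_norm = normalize_saliency(s)
    return SaliencyMap(
        s_map=s, s_norm=s_norm, u_map=saliency_modulation(s_norm),
        sf=sf, sd=sd, sc=sc,
    )
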