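"""JND-guided noise injection, PSNR calibration and quality metrics.

A JND model is validated by hiding noise under its thresholds:

    F_hat(x) = F(x) + beta * r(x) * JND(x)

with r(x) a fair +/-1 coin per pixel per channel and beta a scalar noise
level controller.  Different models are compared at equal noise energy
by calibrating beta so the contaminated image reaches a target PSNR;
bisection on beta with a frozen sign field makes the procedure exact and
reproducible.  PSNR pools the MSE over all three YCbCr planes by default
because the injection perturbs all three.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .base_effects import ThresholdMap
from .config import NoiseConfig
from .errors import CalibrationError, ShapeMismatchError
from .image_io import PlaneImage, YCbCrImage

__all__ = [
    "InjectionResult",
    "QualityScore",
    "inject",
    "psnr",
    "calibrate_beta",
    "ssim",
    "quality_score",
]

_PEAK = 255.0


@dataclass
class InjectionResult:
    """A contaminated image plus the injection bookkeeping."""

    contaminated: YCbCrImage
    beta: float
    achieved_psnr: float
    seed: int
    sign_field_digest: str


@dataclass
class QualityScore:
    """Objective quality of a contaminated image vs its source."""

    psnr_db: float
    ssim: float
    channel_mse: tuple[float, float, float]

    @property
    def mse_shares(self) -> tuple[float, float, float]:
        total = sum(self.channel_mse)
        if total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(m / total for m in self.channel_mse)


def _maps_stack(maps) -> np.ndarray:
    """Accept a (Y, Cb, Cr) map dict/sequence and return a (3, H, W) array."""
    if isinstance(maps, dict):
        seq = [maps[ch] for ch in ("Y", "Cb", "Cr")]
    else:
        seq = list(maps)
    arrs = [np.asarray(getattr(m, "data", m), dtype=np.float64) for m in seq]
    if len(arrs) != 3 or not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ShapeMismatchError("need three aligned threshold maps")
    return np.stack(arrs)


def _sign_field(shape: tuple[int, ...], seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=shape).astype(np.float64) * 2.0 - 1.0


def _contaminate(original: np.ndarray, jnd: np.ndarray, signs: np.ndarray,
                 beta: float) -> np.ndarray:
    return np.clip(original + beta * signs * jnd, 0.0, 255.0)


def _to_image(stack: np.ndarray, like: YCbCrImage) -> YCbCrImage:
    return YCbCrImage(
        PlaneImage(stack[0], "Y"),
        PlaneImage(stack[1], "Cb"),
        PlaneImage(stack[2], "Cr"),
        source_path=like.source_path,
    )


def psnr(a: YCbCrImage, b: YCbCrImage, domain: str = "ycbcr_pooled") -> float:
    """PSNR in dB with MSE pooled over the requested plane set.

    Identical images return ``math.inf``.
    """
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if domain == "y_only":
        diff = a.y.data - b.y.data
    elif domain in {"ycbcr_pooled", "rgb_pooled"}:
        # rgb_pooled is equivalent up to the (orthogonal-ish) transform;
        # both pool all three planes.
        diff = a.stack() - b.stack()
    else:
        raise ValueError(f"unknown psnr domain {domain!r}")
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(_PEAK * _PEAK / mse)


def inject(img: YCbCrImage, maps, beta: float, seed: int,
           config: NoiseConfig | None = None) -> InjectionResult:
    """Add +/- beta * JND noise to every pixel of every channel.

    The sign field is drawn from a seeded generator, independently per
    pixel and per channel; the same seed reproduces the output
    bit-for-bit.  The result is clipped to [0, 255].
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    cfg = config or NoiseConfig()
    jnd = _maps_stack(maps)
    original = img.stack().transpose(2, 0, 1)
    if jnd.shape != original.shape:
        raise ShapeMismatchError(
            f"maps shape {jnd.shape[1:]} does not match image {img.shape}"
        )
    signs = _sign_field(original.shape, seed)
    contaminated = _contaminate(original, jnd, signs, beta)
    out = _to_image(contaminated, img)
    return InjectionResult(
        contaminated=out,
        beta=beta,
        achieved_psnr=psnr(img, out, cfg.psnr_domain),
        seed=seed,
        sign_field_digest=hashlib.sha256(signs.tobytes()).hexdigest()[:16],
    )


def calibrate_beta(img: YCbCrImage, maps, target_psnr: float, seed: int,
                   tol: float = 0.05,
                   config: NoiseConfig | None = None) -> InjectionResult:
    """Find beta so the contaminated image hits ``target_psnr`` +/- tol dB.

    The sign field is frozen from ``seed`` and beta is bisected; clipping
    to [0, 255] is applied inside the loop, so the achieved PSNR honours
    the target even where thresholds exceed the available headroom.
    Raises :class:`CalibrationError` when the maps are identically zero
    or the target is unreachable.
    """
    cfg = config or NoiseConfig()
    jnd = _maps_stack(maps)
    original = img.stack().transpose(2, 0, 1)
    if jnd.shape != original.shape:
        raise ShapeMismatchError(
            f"maps shape {jnd.shape[1:]} does not match image {img.shape}"
        )
    if not np.any(jnd > 0):
        raise CalibrationError("all-zero threshold maps: no noise can be shaped")
    signs = _sign_field(original.shape, seed)

    def achieved(beta: float) -> float:
        out = _to_image(_contaminate(original, jnd, signs, beta), img)
        return psnr(img, out, cfg.psnr_domain)

    lo, hi = 0.0, 1.0
    grow = 0
    while achieved(hi) > target_psnr:
        lo, hi = hi, hi * 2.0
        grow += 1
        if grow > 40:
            raise CalibrationError(
                f"target {target_psnr} dB unreachable: clipping saturates "
                f"at {achieved(hi):.3f} dB (beta={hi:g})"
            )

    beta = hi
    value = achieved(beta)
    for _ in range(cfg.max_iterations):
        if abs(value - target_psnr) <= tol:
            break
        beta = 0.5 * (lo + hi)
        value = achieved(beta)
        if value > target_psnr:
            lo = beta
        else:
            hi = beta
    else:
        raise CalibrationError(
            f"no convergence to {target_psnr} +/- {tol} dB in "
            f"{cfg.max_iterations} iterations; bracket beta in "
            f"[{lo:.6g}, {hi:.6g}], achieved {value:.4f} dB"
        )

    contaminated = _to_image(_contaminate(original, jnd, signs, beta), img)
    return InjectionResult(
        contaminated=contaminated,
        beta=beta,
        achieved_psnr=value,
        seed=seed,
        sign_field_digest=hashlib.sha256(signs.tobytes()).hexdigest()[:16],
    )


def ssim(a: PlaneImage | np.ndarray, b: PlaneImage | np.ndarray) -> float:
    """Single-scale structural similarity on the 8-bit range.

    Gaussian 11x11 window (sigma 1.5), population covariances — the
    conventional parameterisation.
    """
    arr_a = np.asarray(getattr(a, "data", a), dtype=np.float64)
    arr_b = np.asarray(getattr(b, "data", b), dtype=np.float64)
    if arr_a.shape != arr_b.shape:
        raise ShapeMismatchError(f"shape mismatch: {arr_a.shape} vs {arr_b.shape}")
    return float(
        structural_similarity(
            arr_a, arr_b, data_range=_PEAK, gaussian_weights=True,
            sigma=1.5, use_sample_covariance=False,
        )
    )


def quality_score(original: YCbCrImage, contaminated: YCbCrImage,
                  config: NoiseConfig | None = None) -> QualityScore:
    """PSNR, luma SSIM and per-channel MSE of a contaminated image."""
    cfg = config or NoiseConfig()
    mse = tuple(
        float(np.mean((original.plane(ch).data - contaminated.plane(ch).data) ** 2))
        for ch in ("Y", "Cb", "Cr")
    )
    return QualityScore(
        psnr_db=psnr(original, contaminated, cfg.psnr_domain),
        ssim=ssim(original.y, contaminated.y),
        channel_mse=mse,
    )
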