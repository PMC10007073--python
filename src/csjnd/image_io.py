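"""Image containers, file I/O and RGB <-> YCbCr conversion.

All pixel data is held as float64 on the 8-bit intensity scale [0, 255];
quantization to integers happens only when an image file is written.
Coordinates are 0-based (row, col); every local window elsewhere in the
package is odd-sized and centred.

The color transform is full-range BT.601 (the JPEG convention): the
per-channel model constants used downstream originate from literature
built on JPEG-style YCbCr, so studio-range or BT.709 variants would put
the chroma planes on the wrong scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ShapeMismatchError, UnsupportedDepthError

__all__ = [
    "PlaneImage",
    "RGBImage",
    "YCbCrImage",
    "read_rgb",
    "write_rgb",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "write_map",
    "read_map",
]

_VALID_LABELS = {"Y", "Cb", "Cr", "R", "G", "B", "L", "a", "b"}

#: Full-range BT.601 forward matrix, rows produce (Y, Cb, Cr) from (R, G, B).
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_INV = np.linalg.inv(_FWD)


@dataclass
class PlaneImage:
    """One 2-D channel of an 8-bit image held as float.

    Parameters
    ----------
    data : ndarray
        2-D float array, nominal range [0, 255].
    channel_label : str
        One of Y, Cb, Cr, R, G, B, L, a, b.
    """

    data: np.ndarray
    channel_label: str = "Y"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"plane must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] < 5 or self.data.shape[1] < 5:
            raise ValueError(
                f"plane must be at least 5x5 (minimum window support), "
                f"got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("plane contains non-finite values")
        if self.channel_label not in _VALID_LABELS:
            raise ValueError(f"unknown channel label {self.channel_label!r}")
        if self.channel_label in {"Y", "R", "G", "B"}:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 255 + 1e-9:
                raise ValueError(
                    f"{self.channel_label} plane outside [0, 255]: "
                    f"min={lo:.3f}, max={hi:.3f}"
                )

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class RGBImage:
    """Three aligned R, G, B planes from one source image."""

    r: PlaneImage
    g: PlaneImage
    b: PlaneImage
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ShapeMismatchError(
                f"RGB planes disagree in shape: "
                f"{self.r.shape}, {self.g.shape}, {self.b.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    def stack(self) -> np.ndarray:
        """Return an (H, W, 3) float array."""
        return np.stack([self.r.data, self.g.data, self.b.data], axis=-1)

    @classmethod
    def from_array(cls, arr: np.ndarray, source_path: str | None = None) -> "RGBImage":
        """Build from an (H, W, 3) float array on the [0, 255] scale."""
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got {arr.shape}")
        return cls(
            PlaneImage(arr[..., 0], "R"),
            PlaneImage(arr[..., 1], "G"),
            PlaneImage(arr[..., 2], "B"),
            source_path=source_path,
        )


@dataclass
class YCbCrImage:
    """Three aligned Y, Cb, Cr planes from one source image."""

    y: PlaneImage
    cb: PlaneImage
    cr: PlaneImage
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not (self.y.shape == self.cb.shape == self.cr.shape):
            raise ShapeMismatchError(
                f"YCbCr planes disagree in shape: "
                f"{self.y.shape}, {self.cb.shape}, {self.cr.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    def stack(self) -> np.ndarray:
        """Return an (H, W, 3) float array ordered (Y, Cb, Cr)."""
        return np.stack([self.y.data, self.cb.data, self.cr.data], axis=-1)

    def plane(self, channel: str) -> PlaneImage:
        try:
            return {"Y": self.y, "Cb": self.cb, "Cr": self.cr}[channel]
        except KeyError:
            raise ValueError(f"unknown YCbCr channel {channel!r}") from None


def read_rgb(path) -> RGBImage:
    """Read an 8-bit PNG/BMP/TIFF image as three R, G, B planes.

    Grayscale inputs are replicated to three identical planes; an alpha
    channel, if present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by backend
        raise OSError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"{path!s}: only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"{path!s}: unsupported channel layout {arr.shape}")
    return RGBImage.from_array(arr.astype(np.float64), source_path=str(path))


def quantize_u8(arr: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to [0, 255] uint8."""
    q = np.floor(np.abs(arr) + 0.5) * np.sign(arr)
    return np.clip(q, 0, 255).astype(np.uint8)


def write_rgb(img: RGBImage, path) -> None:
    """Write an RGB image as 8-bit PNG (or whatever the suffix selects)."""
    iio.imwrite(path, quantize_u8(img.stack()))


def rgb_to_ycbcr(rgb: RGBImage) -> YCbCrImage:
    """Full-range BT.601: Y in [0, 255], Cb/Cr centred on 128, clipped."""
    arr = rgb.stack()
    ycc = arr @ _FWD.T
    ycc[..., 1] += 128.0
    ycc[..., 2] += 128.0
    ycc = np.clip(ycc, 0.0, 255.0)
    return YCbCrImage(
        PlaneImage(ycc[..., 0], "Y"),
        PlaneImage(ycc[..., 1], "Cb"),
        PlaneImage(ycc[..., 2], "Cr"),
        source_path=rgb.source_path,
    )


def ycbcr_to_rgb(img: YCbCrImage) -> RGBImage:
    """Inverse full-range BT.601; output clipped to [0, 255]."""
    ycc = img.stack().copy()
    ycc[..., 1] -= 128.0
    ycc[..., 2] -= 128.0
    arr = np.clip(ycc @ _INV.T, 0.0, 255.0)
    return RGBImage.from_array(arr, source_path=img.source_path)


def write_map(data, path) -> None:
    """Write a threshold/saliency map as single-plane float32 TIFF.

    Accepts a bare 2-D array or any object with a 2-D ``.data`` attribute.
    The round trip through :func:`read_map` is bitwise at float32.
    """
    arr = np.asarray(getattr(data, "data", data), dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError(f"map must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("map contains non-finite values")
    tifffile.imwrite(path, arr)


def read_map(path) -> np.ndarray:
    """Read a float32 TIFF map written by :func:`write_map`."""
    return tifffile.imread(path)
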