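"""Deterministic synthetic test stimuli with known analytic properties.

Every stage of the model has at least one stimulus here whose expected
behaviour can be written in closed form:

* ``flat`` — zero contrast and no orientations anywhere, so the final
  threshold is exactly the (weighted) luminance-adaptation value;
* ``ramp`` — a smooth luminance gradient exercising the adaptation
  curve across its range without strong edges;
* ``grating`` — a sinusoid with a single known orientation bin;
* ``checkerboard`` — two orthogonal orientations and strong contrast;
* ``step_edge`` — one straight edge at a known location for the Canny
  weight and directional gradients;
* ``random_texture`` — seeded dense i.i.d. texture, the worst case for
  pattern complexity and the workhorse for oracle-equivalence checks;
* ``two_region`` — one flat half and one textured half, separating the
  behaviour of saliency modulation and noise allocation spatially.

Generation is a pure function of the spec (seed included), so fixtures
are bit-stable across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .image_io import RGBImage

__all__ = ["FixtureSpec", "generate", "fixture_suite", "KINDS"]

KINDS = (
    "flat",
    "ramp",
    "grating",
    "checkerboard",
    "step_edge",
    "random_texture",
    "two_region",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic stimulus."""

    kind: str
    size: tuple[int, int] = (128, 128)
    params: Mapping[str, float | int | str] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        h, w = self.size
        if h < 16 or w < 16:
            raise ValueError(f"fixture must be at least 16x16, got {self.size}")


def _gray(img: np.ndarray) -> np.ndarray:
    """Replicate a 2-D gray field to (H, W, 3)."""
    return np.repeat(img[..., None], 3, axis=2)


def _flat(h: int, w: int, p: Mapping) -> np.ndarray:
    return _gray(np.full((h, w), float(p.get("level", 128.0))))


def _ramp(h: int, w: int, p: Mapping) -> np.ndarray:
    lo = float(p.get("low", 16.0))
    hi = float(p.get("high", 240.0))
    horizontal = str(p.get("orientation", "horizontal")) == "horizontal"
    n = w if horizontal else h
    line = np.linspace(lo, hi, n)
    img = np.tile(line, (h, 1)) if horizontal else np.tile(line[:, None], (1, w))
    return _gray(img)


def _grating(h: int, w: int, p: Mapping) -> np.ndarray:
    period = float(p.get("period", 8.0))
    angle = np.deg2rad(float(p.get("angle", 0.0)))
    amplitude = float(p.get("amplitude", 60.0))
    mean = float(p.get("mean", 128.0))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # angle = gradient orientation: 0 gives vertical stripes (variation
    # along x, quantised orientation bin 0)
    phase = (xx * np.cos(angle) + yy * np.sin(angle)) * 2.0 * np.pi / period
    img = mean + amplitude * np.sin(phase)
    return _gray(np.clip(img, 0.0, 255.0))


def _checkerboard(h: int, w: int, p: Mapping) -> np.ndarray:
    block = int(p.get("block", 8))
    lo = float(p.get("low", 64.0))
    hi = float(p.get("high", 192.0))
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.where(((yy // block) + (xx // block)) % 2 == 0, lo, hi)
    return _gray(img.astype(np.float64))


def _step_edge(h: int, w: int, p: Mapping) -> np.ndarray:
    lo = float(p.get("low", 0.0))
    hi = float(p.get("high", 255.0))
    horizontal = str(p.get("orientation", "horizontal")) == "horizontal"
    img = np.full((h, w), lo)
    if horizontal:  # edge line runs horizontally: top half lo, bottom half hi
        img[h // 2:, :] = hi
    else:
        img[:, w // 2:] = hi
    return _gray(img)


def _random_texture(h: int, w: int, p: Mapping) -> np.ndarray:
    rng = np.random.default_rng(int(p.get("seed", 0)))
    return rng.integers(0, 256, size=(h, w, 3)).astype(np.float64)


def _two_region(h: int, w: int, p: Mapping) -> np.ndarray:
    level = float(p.get("level", 128.0))
    rng = np.random.default_rng(int(p.get("seed", 0)))
    img = np.full((h, w, 3), level)
    img[:, w // 2:, :] = rng.integers(0, 256, size=(h, w - w // 2, 3))
    return img


_GENERATORS = {
    "flat": _flat,
    "ramp": _ramp,
    "grating": _grating,
    "checkerboard": _checkerboard,
    "step_edge": _step_edge,
    "random_texture": _random_texture,
    "two_region": _two_region,
}


def generate(spec: FixtureSpec) -> RGBImage:
    """Generate the RGB stimulus described by ``spec`` (deterministic)."""
    h, w = spec.size
    arr = _GENERATORS[spec.kind](h, w, spec.params)
    return RGBImage.from_array(arr)


def fixture_suite() -> list[FixtureSpec]:
    """The canonical 12-stimulus regression set.

    Covers every kind at 128x128 and 128x192 with fixed seeds; small
    enough that the full pipeline runs in well under a second per image
    while still exercising every window in the model.
    """
    return [
        FixtureSpec("flat", (128, 128), {"level": 128},
                    "mid-gray flat field: threshold = LA exactly"),
        FixtureSpec("flat", (128, 128), {"level": 32},
                    "dark flat field: high luminance-adaptation threshold"),
        FixtureSpec("ramp", (128, 128), {"low": 16, "high": 240},
                    "horizontal luminance ramp across the adaptation curve"),
        FixtureSpec("grating", (128, 128), {"period": 8, "angle": 0},
                    "vertical-stripe sinusoid, one orientation bin"),
        FixtureSpec("grating", (128, 192), {"period": 12, "angle": 45},
                    "oblique sinusoid at 45 degrees"),
        FixtureSpec("checkerboard", (128, 128), {"block": 8},
                    "checkerboard: two orientations, strong contrast"),
        FixtureSpec("step_edge", (128, 128), {"orientation": "horizontal"},
                    "single horizontal step edge"),
        FixtureSpec("step_edge", (128, 192), {"orientation": "vertical"},
                    "single vertical step edge"),
        FixtureSpec("random_texture", (128, 128), {"seed": 7},
                    "dense seeded color texture"),
        FixtureSpec("random_texture", (128, 192), {"seed": 11},
                    "dense seeded color texture, wide"),
        FixtureSpec("two_region", (128, 128), {"seed": 5},
                    "flat left half, textured right half"),
        FixtureSpec("two_region", (128, 192), {"seed": 13},
                    "flat left half, textured right half, wide"),
    ]
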