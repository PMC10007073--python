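"""Model configuration.

Every constant of the model lives here so that each stage can be driven
from a single key-value config (YAML) and so the effective parameters can
be dumped next to the outputs.  Defaults are the published operating
point of the model; see docs/methods.md for why each value is what it is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

__all__ = [
    "BaseEffectsConfig",
    "StructureConfig",
    "SaliencyConfig",
    "ColorConfig",
    "NoiseConfig",
    "ModelConfig",
    "VARIANTS",
]

#: Model variants: "B" = luminance adaptation + masking only (basic),
#: "S" = basic + saliency modulation, "C" = basic + color-sensitivity
#: weights, "full" = both.
VARIANTS = ("B", "S", "C", "full")


@dataclass
class BaseEffectsConfig:
    """Luminance adaptation and contrast masking."""

    window: int = 5          # odd local-statistics window, pixels
    a1: float = 16.0         # contrast-masking gain
    a2: float = 26.0         # contrast-masking half-saturation, gray levels
    contrast_stat: str = "std"   # {"std", "var"} semantics of c(x)
    weighted_mean: bool = False  # Gaussian-weighted background mean


@dataclass
class StructureConfig:
    """Pattern masking and edge protection."""

    n_bins: int = 12             # orientation bins over [0, 180) degrees
    region_window: int = 5       # odd histogram region, pixels
    mag_threshold: float = 2.0   # gradient magnitude below which a pixel
    #                              has no defined orientation (gray levels)
    b1: float = 0.8              # pattern-masking gain
    b2: float = 2.7              # pattern-masking exponent
    b3: float = 0.1              # pattern-masking regulariser
    canny_sigma: float = 1.4
    canny_low: float = 0.1       # hysteresis thresholds on normalised
    canny_high: float = 0.3      # gradient magnitude, in [0, 1]
    smooth_window: int = 7       # odd Gaussian window for the edge weight
    smooth_sigma: float = 0.8
    edge_value: float = 0.1      # weight assigned on the edge line
    edge_source: str = "per_channel"  # {"per_channel", "luma"} plane used
    #                                   for G(x) and the Canny map
    lambda_y: float = 0.117      # per-channel edge-protection gains
    lambda_cb: float = 0.65
    lambda_cr: float = 0.45

    def lambda_for(self, channel: str) -> float:
        try:
            return {"Y": self.lambda_y, "Cb": self.lambda_cb,
                    "Cr": self.lambda_cr}[channel]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None


@dataclass
class SaliencyConfig:
    """SDSP-style saliency detection and the modulation factor."""

    enabled: bool = True
    omega0: float = 0.002    # log-Gabor centre frequency (cycles/pixel)
    sigma_f: float = 6.2     # log-Gabor bandwidth (log units)
    sigma_d: float = 114.0   # location-prior spread, pixels at working size
    sigma_c: float = 0.25    # color-prior spread, normalised chroma units
    working_size: int = 256  # longer image side during saliency detection


@dataclass
class ColorConfig:
    """Color-sensitivity weighting of the Y/Cb/Cr sub-thresholds."""

    d_ratio: tuple[float, float, float] = (1.0, 0.432, 0.501)
    # Critical viewing-distance ratio D_Y : D_Cb : D_Cr at which distortion
    # in each component stops being perceptible.
    cs_from: str = "printed"  # {"printed", "unrounded"}: whether weights
    # are derived from the 3-decimal sensitivity parameters (matching the
    # published triple) or from full-precision area shares.


@dataclass
class NoiseConfig:
    """JND-guided noise injection and quality metrics."""

    psnr_domain: str = "ycbcr_pooled"  # {"ycbcr_pooled", "y_only", "rgb_pooled"}
    calibration_tol: float = 0.05      # dB
    max_iterations: int = 60


@dataclass
class ModelConfig:
    """Top-level configuration for the whole JND pipeline."""

    alpha: float = 0.3          # gain-reduction factor of the NAMM fusion
    variant: str = "full"       # one of VARIANTS
    la_source: str = "luma"     # {"luma", "per_channel"} plane whose local
    #                             mean drives luminance adaptation
    base: BaseEffectsConfig = field(default_factory=BaseEffectsConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    color: ColorConfig = field(default_factory=ColorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["color"]["d_ratio"] = list(d["color"]["d_ratio"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "base": BaseEffectsConfig,
            "structure": StructureConfig,
            "saliency": SaliencyConfig,
            "color": ColorConfig,
            "noise": NoiseConfig,
        }
        valid = {f.name for f in fields(cls)}
        for key, value in d.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if key in sections:
                sub = sections[key]
                sub_valid = {f.name for f in fields(sub)}
                bad = set(value) - sub_valid
                if bad:
                    raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
                if key == "color" and "d_ratio" in value:
                    value = {**value, "d_ratio": tuple(value["d_ratio"])}
                kwargs[key] = sub(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
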