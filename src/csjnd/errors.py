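"""Exception hierarchy for csjnd."""


class CsjndError(Exception):
    """Base class for all csjnd-specific errors."""


class ShapeMismatchError(CsjndError, ValueError):
    """Two maps or planes that must be aligned have different shapes."""


class ChannelMismatchError(CsjndError, ValueError):
    """A map carries a channel label incompatible with the operation."""


class UnsupportedDepthError(CsjndError, ValueError):
    """The decoded image is not 8-bit."""


class CalibrationError(CsjndError, RuntimeError):
    """Noise-level calibration could not reach the requested PSNR."""
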