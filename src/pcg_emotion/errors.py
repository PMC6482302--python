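"""Exception hierarchy for the pcg_emotion toolkit."""


class PcgEmotionError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(PcgEmotionError):
    """Invalid or unknown configuration keys/values."""


class SignalError(PcgEmotionError):
    """Malformed or degenerate signal input."""


class InsufficientCyclesError(PcgEmotionError):
    """Fewer complete cardiac cycles than the operation requires."""


class SegmentationError(PcgEmotionError):
    """Boundary detection produced no invariant-consistent result."""
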