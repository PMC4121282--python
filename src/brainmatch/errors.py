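"""Exception hierarchy for the brainmatch pipeline."""


class BrainMatchError(Exception):
    """Base class for all brainmatch errors."""


class LoadError(BrainMatchError):
    """A volume or prior set could not be read or failed validation."""


class RegistrationError(BrainMatchError):
    """Rigid registration failed (no overlap, divergence, degenerate matrix)."""


class SegmentationError(BrainMatchError):
    """Tissue classification or gray-matter extraction failed."""


class MatchingError(BrainMatchError):
    """Chamfer matching or score normalization failed."""


class ConfigError(BrainMatchError):
    """Invalid pipeline configuration."""
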