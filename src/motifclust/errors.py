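"""Exception types shared across the package."""


class MotifClustError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MotifClustError):
    """A network or pattern file could not be parsed."""


class ValidationError(MotifClustError, ValueError):
    """An input violates a documented precondition."""


class PatternSetError(ValidationError):
    """A motif pattern set violates the no-mutual-subisomorphism rule."""


class ClassificationError(MotifClustError):
    """A clustered motif pair matched no catalog entry (internal inconsistency)."""


class SamplingError(MotifClustError):
    """A rejection sampler exhausted its restart budget."""
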