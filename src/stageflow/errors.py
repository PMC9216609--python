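"""Exception types shared across the package."""


class StageflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StageflowError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(StageflowError, ValueError):
    """Data violates a domain invariant (ordering, bounds, stochasticity...)."""
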