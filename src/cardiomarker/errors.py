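"""Exception types shared across the package."""


class CardiomarkerError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CardiomarkerError):
    """A domain object or input file violates an invariant."""


class FormatError(CardiomarkerError):
    """An on-disk artifact does not follow the expected dialect."""


class AnalysisError(CardiomarkerError):
    """An analysis operation was asked to run on unusable input."""
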