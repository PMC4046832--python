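"""Exception types shared across the package."""


class ChromcauseError(Exception):
    """Base class for package errors."""


class FormatError(ChromcauseError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ChromcauseError):
    """Input data violates a documented precondition or invariant."""
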