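"""Exception types shared across the pipeline."""


class EndEegError(Exception):
    """Base class for all package errors."""


class ValidationError(EndEegError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(EndEegError, ValueError):
    """A file does not conform to the expected on-disk dialect."""
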