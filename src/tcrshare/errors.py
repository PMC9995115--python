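"""Exception hierarchy used across the package."""


class TcrshareError(Exception):
    """Base class for all package errors."""


class FormatError(TcrshareError):
    """A file does not conform to the expected table/model format."""


class ValidationError(TcrshareError):
    """Input values violate a documented precondition."""


class GenerationError(TcrshareError):
    """A synthetic generator could not satisfy its constraints."""
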