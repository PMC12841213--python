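"""Exception hierarchy shared across the pipeline."""


class IltcError(Exception):
    """Base class for all package errors."""


class FormatError(IltcError, ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(IltcError, ValueError):
    """Input content violates a contract (enums, dimensions, NaNs...)."""


class ParameterError(IltcError, ValueError):
    """A caller-supplied parameter is outside its valid domain."""
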