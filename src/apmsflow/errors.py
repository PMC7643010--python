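"""Exception hierarchy shared across modules."""


class ApmsflowError(Exception):
    """Base class for all package errors."""


class ParseError(ApmsflowError):
    """A file could not be parsed; message names the offending record/line."""


class SchemaError(ApmsflowError):
    """A tabular input is missing required columns."""


class ValidationError(ApmsflowError):
    """A domain object violates one of its invariants."""


class DegenerateInputError(ApmsflowError):
    """Statistical input is degenerate (e.g. both sample variances zero)."""


class ConfigError(ApmsflowError):
    """Run configuration is invalid or references missing inputs."""
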