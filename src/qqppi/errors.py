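"""Exception hierarchy shared across the pipeline."""


class QQPPIError(Exception):
    """Base class for all package errors."""


class ParameterError(QQPPIError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(QQPPIError, ValueError):
    """Malformed input file content; the message locates the defect."""


class PreconditionError(QQPPIError, ValueError):
    """An operation was called on data that violates its contract."""
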