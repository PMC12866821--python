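"""Exception hierarchy shared by all pipeline stages."""


class VdlinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VdlinError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(VdlinError):
    """Input data does not match the expected shape, columns or gene set."""


class EmptyInputError(VdlinError):
    """An operation that requires at least one record received none."""


class SmilesParseError(VdlinError):
    """A SMILES string could not be parsed.

    ``position`` is the 0-based character offset at which parsing failed,
    or ``None`` when the failure is global (e.g. chemistry-level rejection).
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class SequenceLengthError(VdlinError):
    """A rule sequence exceeds the grammar's maximum sequence length."""


class NotFittedError(VdlinError):
    """A model/encoder was used before being fitted."""


class NumericalError(VdlinError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
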