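"""Exception hierarchy for the pipeline."""


class LongcloneError(Exception):
    """Base class for all package errors."""


class ParseError(LongcloneError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(LongcloneError):
    """A parsed record violates the schema (missing field, bad value)."""


class ValidationError(LongcloneError):
    """Records are individually well-formed but jointly inconsistent."""


class ParameterError(LongcloneError):
    """A numeric parameter is outside its admissible range."""


class InsufficientDataError(LongcloneError):
    """Not enough observations to compute the requested estimate."""


class UndefinedTestError(LongcloneError):
    """A statistical test is undefined for the given input (e.g. empty table)."""


class ConfigError(LongcloneError):
    """Run or simulation configuration is invalid."""


class StageError(LongcloneError):
    """A pipeline stage failed; the message names the stage."""
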