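"""Exception hierarchy shared across the pipeline stages."""


class FociMetaError(Exception):
    """Base class for all focimeta errors."""


class SchemaError(FociMetaError):
    """Input file is missing required columns or headers."""


class FociParseError(FociMetaError):
    """A row of an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(FociMetaError):
    """Parsed values violate a domain invariant (bounds, labels, spaces)."""


class ConfigError(FociMetaError):
    """An option or parameter value is outside its admissible range."""


class EmptyInputError(FociMetaError):
    """An operation requiring a non-empty table received an empty one."""


class DegenerateTableError(FociMetaError):
    """A contingency table cannot support the requested test (zero margin)."""


class GenerationError(FociMetaError):
    """The synthetic-foci generator received an infeasible specification."""


class StageError(FociMetaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
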