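"""Exception types shared across the pipeline."""


class MigflowError(Exception):
    """Base class for all package errors."""


class SchemaError(MigflowError):
    """A tabular input is missing a required column or has a malformed header."""


class ValidationError(MigflowError):
    """A value in an otherwise well-formed table violates a documented invariant."""


class ConfigError(MigflowError):
    """A scenario or run configuration violates its invariants."""


class PipelineError(MigflowError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
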