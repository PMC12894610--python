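"""Exception hierarchy shared across the package."""


class AffectDimError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AffectDimError, ValueError):
    """A table is structurally malformed (missing/unknown columns)."""


class ValidationError(AffectDimError, ValueError):
    """A table is structurally fine but violates a value invariant."""


class PipelineError(AffectDimError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
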