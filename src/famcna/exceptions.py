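"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration value is out of its domain."""


class GenerationError(RuntimeError):
    """Synthetic-data generation failed (e.g. overlapping planted events)."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested operation (e.g. all samples
    identical when a two-branch split is required)."""


class MatrixFormatError(ValueError):
    """A tab-delimited matrix file violates the format contract."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
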