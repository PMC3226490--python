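"""Exception types shared across the package."""


class FacohortError(Exception):
    """Base class for package errors."""


class ConfigError(FacohortError):
    """Invalid or incomplete configuration."""


class SchemaError(FacohortError):
    """A table violates its declared schema (bad level, missing column, bad id)."""


class SeparationError(FacohortError):
    """Complete or quasi-complete separation in a logistic-type fit."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []
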