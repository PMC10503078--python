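"""Exception hierarchy for input handling and model calibration."""


class CheriskError(Exception):
    """Base class for all package-specific errors."""


class InputError(CheriskError):
    """Base class for problems with input tables."""

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        ctx = []
        if file is not None:
            ctx.append(f"file={file}")
        if row is not None:
            ctx.append(f"row={row}")
        if column is not None:
            ctx.append(f"column={column}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)
        self.file = file
        self.row = row
        self.column = column


class SchemaError(InputError):
    """CSV header or cell does not match the documented schema."""


class RangeError(InputError):
    """A value is outside its documented valid range."""


class ImputationError(InputError):
    """Regional-average imputation is impossible (whole region missing)."""


class DegenerateGradientError(InputError):
    """A wealth-quintile gradient has zero mean and cannot be rescaled."""


class SeriesLookupError(InputError):
    """CPI or FX series lacks a requested year or currency."""


class LinkageError(InputError):
    """A (country, service) pair cannot be resolved to model inputs."""


class CalibrationError(CheriskError):
    """Income-distribution calibration failed (e.g. unattainable Gini)."""
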