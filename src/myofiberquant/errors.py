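"""Exception hierarchy for the whole pipeline.

Every module raises subclasses of :class:`MyofiberquantError` so callers
(and the CLI) can distinguish user/configuration problems from contract
violations of pluggable backends.
"""


class MyofiberquantError(Exception):
    """Base class for all package errors."""


class FormatError(MyofiberquantError):
    """A file's content does not match the expected format."""


class ParseError(MyofiberquantError):
    """A string or file could not be parsed."""


class CapacityError(MyofiberquantError):
    """A value exceeds the capacity of the target encoding."""


class ParameterError(MyofiberquantError):
    """An invalid parameter value was supplied."""


class ExtentError(MyofiberquantError):
    """A geometry lies (partly) outside the allowed extent."""


class ConsistencyError(MyofiberquantError):
    """Two inputs that must agree (shape, frame, grid) do not."""


class ContractViolationError(MyofiberquantError):
    """A pluggable backend returned output violating its contract."""


class CapabilityError(MyofiberquantError):
    """A requested optional capability (e.g. a backend) is unavailable."""


class DegenerateGeometryError(MyofiberquantError):
    """A polygon is degenerate (collinear, < 3 vertices, zero area)."""


class UndefinedInputError(MyofiberquantError):
    """The requested quantity is undefined for this input (e.g. IoU of two empty masks)."""


class TrainingError(MyofiberquantError):
    """A classifier cannot be trained from the given data."""


class EmptySectionError(MyofiberquantError):
    """A section-level summary was requested for zero fibers."""


class StageError(MyofiberquantError):
    """A pipeline stage failed."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class ConfigError(MyofiberquantError):
    """Invalid pipeline configuration."""
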