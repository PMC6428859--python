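"""Exception hierarchy.

Errors are split by where they surface in a run: configuration problems
(bad paths, impossible parameter combinations), data problems (malformed
files, degenerate outlines, mismatched labels) and numerical failures
(singular covariance matrices, non-SPD rate matrices).  The command-line
layer maps these onto distinct exit codes.
"""


class MorphoratesError(Exception):
    """Base class for all package errors."""


class ConfigError(MorphoratesError, ValueError):
    """Invalid run configuration (paths, counts, modes)."""


class DataError(MorphoratesError, ValueError):
    """Invalid or inconsistent input data."""


class TPSParseError(DataError):
    """Malformed TPS outline file."""


class InvalidOutlineError(DataError):
    """Outline that cannot support Fourier analysis (too few points, zero perimeter)."""


class DegenerateShapeError(DataError):
    """Shape whose first-harmonic ellipse is degenerate; normalization undefined."""


class NumericalError(MorphoratesError, ArithmeticError):
    """Numerical failure: singular/ill-conditioned matrix, non-SPD rate matrix."""


class StageError(MorphoratesError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
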