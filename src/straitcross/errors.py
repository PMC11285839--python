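"""Exception types shared across the pipeline."""


class StraitCrossError(Exception):
    """Base class for all package errors."""


class InputError(StraitCrossError, ValueError):
    """Invalid or malformed input data."""


class UndefinedBearingError(StraitCrossError, ValueError):
    """Bearing requested between coincident points."""


class RankDeficientError(StraitCrossError, ValueError):
    """Design matrix is not full rank; carries the first aliased column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient: column {column!r} is aliased")


class ConvergenceError(StraitCrossError, RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class SeparationError(StraitCrossError, ValueError):
    """Binary response is constant (or separable) within the stratum."""


class InsufficientDataError(StraitCrossError, ValueError):
    """Stratum has too few clusters/observations for the requested model."""
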