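"""Exception hierarchy for the dnamech analysis pipeline.

Every error raised by the library derives from :class:`DnamechError`, so
callers can catch one base class at pipeline boundaries.  Subclasses also
inherit from ``ValueError`` where the failure is a bad input value, which
keeps them compatible with generic validation handling.
"""


class DnamechError(Exception):
    """Base class for all dnamech errors."""


class PoleError(DnamechError, ValueError):
    """Evaluation requested at or beyond a model pole/asymptote."""


class InvalidParameterError(DnamechError, ValueError):
    """Model or smoothing parameters violate their invariants."""


class InitializationError(DnamechError, ValueError):
    """Automatic fit initialization failed on a degenerate curve."""


class ConvergenceError(DnamechError, RuntimeError):
    """Nonlinear fit did not converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DomainError(DnamechError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class SolverError(DnamechError, RuntimeError):
    """Root bracketing or polishing failed."""


class WindowError(DnamechError, ValueError):
    """A force/extension selection window selects too few or no data."""


class DegenerateGridError(DnamechError, ValueError):
    """Duplicate or non-increasing abscissae where a strict grid is required."""


class ReadoutError(DnamechError, ValueError):
    """Inverse force->extension readout outside the monotone data range."""


class CoverageError(DnamechError, ValueError):
    """A requested force grid is not covered by the supplied curves."""


class SegmentationError(DnamechError, ValueError):
    """No phase transitions could be detected in a kinetic trace."""


class UnderdeterminedError(DnamechError, ValueError):
    """Too few distinct observations to determine the requested parameters."""


class TrimError(DnamechError, ValueError):
    """Half-maximum endpoint trimming left fewer than two trace points."""


class ConstructionError(DnamechError, ValueError):
    """Synthetic curve branches cannot be joined into a continuous curve."""


class FormatError(DnamechError, ValueError):
    """A table or config file violates the documented format."""
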