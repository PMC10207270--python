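"""Exception and warning types shared across the package."""


class TetrelScanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TetrelScanError):
    """A structure file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(TetrelScanError):
    """No backbone carbonyl could be extracted from the input."""


class InsufficientDataError(TetrelScanError):
    """Too few data points for the requested fit."""


class DegenerateFitError(TetrelScanError):
    """The predictor values carry no variance; a line cannot be fitted."""


class FitError(TetrelScanError):
    """Nonlinear fit failed to converge."""


class UnsupportedElementError(TetrelScanError):
    """Element without tabulated promolecular parameters."""


class RosterMismatchWarning(UserWarning):
    """Frames of an ensemble do not share an identical carbonyl roster."""


class ExtrapolationWarning(UserWarning):
    """A density value lies outside the calibrated range."""


class MissingAtomWarning(UserWarning):
    """A residue lacks one of the backbone atoms needed for analysis."""
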