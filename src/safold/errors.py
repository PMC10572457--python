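"""Exception hierarchy for safold."""


class SafoldError(Exception):
    """Base class for all safold errors."""


class ParseError(SafoldError):
    """A structure or sequence file could not be parsed."""


class ChainNotFoundError(SafoldError):
    """The requested chain id is absent from the structure."""


class CalibrationError(SafoldError):
    """A scoring model could not be calibrated.

    Raised when the expected background score of a substitution matrix is
    non-negative (Karlin-Altschul statistics undefined) or no positive score
    exists.  The message states which direction to adjust sigma / the scores.
    """
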