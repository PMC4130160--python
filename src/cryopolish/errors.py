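"""Exception hierarchy for cryopolish.

All errors raised by the library derive from :class:`CryoPolishError` so callers
can catch one base class at tool boundaries.
"""


class CryoPolishError(Exception):
    """Base class for all cryopolish errors."""


class FormatError(CryoPolishError):
    """A file does not conform to the expected on-disk format."""


class ShapeError(CryoPolishError):
    """An array has the wrong shape (non-square image, non-cubic volume, mismatch)."""


class ParameterError(CryoPolishError):
    """A parameter violates its documented constraints."""


class AlignmentError(CryoPolishError):
    """Translational alignment is impossible (e.g. zero-variance input)."""


class TrackFitError(CryoPolishError):
    """The weighted least-squares track fit is degenerate for a particle."""


class UnfittableFrameError(CryoPolishError):
    """Too few valid shells to fit a relative Guinier line for a frame."""


class MissingInputError(CryoPolishError):
    """A dataset-level operation is missing a per-particle input (track/weights)."""

    def __init__(self, message, missing_ids=()):
        super().__init__(message)
        self.missing_ids = list(missing_ids)
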