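"""Exception hierarchy.

All argument-validation failures derive from :class:`InvalidArgumentError`
(itself a ``ValueError``) so callers can catch one type at the API surface.
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(InvalidArgumentError):
    """The regression design matrix is rank deficient (too few distinct x)."""


class EmptySegmentationError(InvalidArgumentError):
    """A mask has no foreground pixels.  Carries the offending frame id."""

    def __init__(self, message: str, frame_id: int | None = None):
        super().__init__(message)
        self.frame_id = frame_id


class TrackingGapError(InvalidArgumentError):
    """No edge pixels inside the ROI for some frame.  Carries the frame id."""

    def __init__(self, message: str, frame_id: int | None = None):
        super().__init__(message)
        self.frame_id = frame_id


class NoCyclesError(InvalidArgumentError):
    """No breathing cycles detectable in a displacement trace."""


class SynchronizationError(InvalidArgumentError):
    """Surrogate and ground-truth streams cannot be aligned."""
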