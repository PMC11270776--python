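"""Exception hierarchy for the extraction pipelines.

Invalid arguments raise plain :class:`ValueError`; the classes below mark
data-dependent failure modes a caller may want to catch separately.
"""


class PipelineError(Exception):
    """Base class for data-dependent pipeline failures."""


class NoSignalError(PipelineError):
    """Every spectrogram column has zero weight above the intensity floor."""


class NoCycleError(PipelineError):
    """Fewer than one complete cardiac cycle could be identified."""


class TrackingLostError(PipelineError):
    """Contour tracking failed: too many rays without a usable edge."""


class UndecodableFrameError(PipelineError):
    """A frame decodes no pixels and has no temporal neighbour to borrow from."""


class CalibrationError(PipelineError):
    """Relative-to-absolute velocity calibration is impossible (zero mean flow)."""


class MissingSystolicTimeError(PipelineError):
    """A pulse without reverse flow needs a manually supplied systolic time."""


class EmptySupportError(PipelineError):
    """All points were excluded from a comparison metric's support."""


class ConvergenceError(PipelineError):
    """Iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
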