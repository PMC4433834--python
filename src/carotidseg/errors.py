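"""Exception hierarchy shared by all pipeline stages."""


class CarotidSegError(Exception):
    """Base class for all package errors."""


class ParameterError(CarotidSegError, ValueError):
    """A parameter violates its documented bounds or shape contract."""


class DegenerateInputError(CarotidSegError, ValueError):
    """Input has no usable signal (e.g. constant image where contrast is required)."""


class InsufficientDataError(CarotidSegError, ValueError):
    """Not enough data to perform the operation (e.g. < 2 QRS complexes)."""


class DetectionError(CarotidSegError, RuntimeError):
    """A detection stage found no acceptable hypothesis.

    ``reason`` carries a machine-readable code (e.g. ``"hough_no_peak"``) that
    pipeline reports record verbatim.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class VideoIOError(CarotidSegError, IOError):
    """A video/frame source could not be read."""
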