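"""Exception hierarchy for the screening pipeline."""


class OculoscreenError(Exception):
    """Base class for all package errors."""


class InvalidSceneError(OculoscreenError):
    """Synthetic scene geometry falls outside the image frame."""


class InvalidInputError(OculoscreenError):
    """Malformed or empty input image/array."""


class NoPupilFoundError(OculoscreenError):
    """Binarization produced no dark component above the minimum area."""


class UntraceableError(OculoscreenError):
    """Connected component cannot be contour-traced."""


class FitFailureError(OculoscreenError):
    """Ellipse fit failed (degenerate or collinear points)."""


class CanthusNotFoundError(OculoscreenError):
    """Fewer than two stable canthus candidates in a frame."""


class AlignmentError(OculoscreenError):
    """Per-eye frame streams have mismatched lengths."""


class UndefinedEError(OculoscreenError):
    """Projection statistic undefined (coincident canthi)."""


class ConfigError(OculoscreenError):
    """Invalid or unknown configuration."""


class EmptyReportError(OculoscreenError):
    """Metrics requested on an all-zero confusion matrix."""
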