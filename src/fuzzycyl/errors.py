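"""Exception hierarchy for fuzzy cylinder fitting."""


class FuzzyCylError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(FuzzyCylError):
    """A geometric configuration is degenerate (zero range, point on axis, ...)."""


class InvalidCovarianceError(FuzzyCylError):
    """A covariance matrix is not symmetric positive-definite."""


class InvalidPrecisionError(FuzzyCylError):
    """A precision matrix is not symmetric positive-definite."""


class IllConditionedError(FuzzyCylError):
    """A covariance is too close to singular to whiten reliably."""


class EnvelopeTooSmallError(FuzzyCylError):
    """Fewer than three tangent lines were requested for the envelope."""


class DegenerateLineError(FuzzyCylError):
    """A tangent line is degenerate (tangent point at the circle center)."""


class EmptyScanError(FuzzyCylError):
    """A simulated scan produced no hit points."""


class EmptyCloudError(FuzzyCylError):
    """An operation received an empty (fuzzy) point cloud."""


class FitFailureError(FuzzyCylError):
    """A fitting routine failed to produce a valid geometry.

    Carries ``best_result`` when a partial iterate is available.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class PointCloudParseError(FuzzyCylError):
    """A point cloud file could not be parsed; carries the offending record index."""

    def __init__(self, message, record=None):
        super().__init__(message)
        self.record = record
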