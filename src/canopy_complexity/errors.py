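"""Exception hierarchy.

All package errors derive from :class:`CanopyComplexityError` so callers can
catch everything the library raises with a single clause.
"""

from __future__ import annotations


class CanopyComplexityError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CanopyComplexityError):
    """A file could not be read or parsed in the declared format."""


class EmptyCloudError(CanopyComplexityError):
    """An operation received or produced a point cloud with no points."""


class DegenerateExtentError(CanopyComplexityError):
    """All points coincide; the voxel grid has zero extent."""


class InsufficientScalesError(CanopyComplexityError):
    """Too few voxel-halving scales above the minimum voxel size to fit
    the log-log regression after the first scale is excluded."""


class InsufficientPointsError(CanopyComplexityError):
    """Fewer points than the operation needs (e.g. < 2 for nearest
    neighbours)."""


class DegenerateDataError(CanopyComplexityError):
    """Zero variance, zero range, or zero covariance where a regression or
    correlation requires otherwise."""


class FitError(CanopyComplexityError):
    """A nonlinear fit failed to converge.

    Carries the log-log fallback estimate in ``fallback`` when available.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class SDBConvergenceError(CanopyComplexityError):
    """Sampling-density-bias correction hit the iteration cap with a trend
    still detected. Carries the partial report in ``report``."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class PipelineError(CanopyComplexityError):
    """The batch pipeline produced no successful result rows."""
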