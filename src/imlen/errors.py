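"""Exception hierarchy and warning categories.

Every named failure mode raises a distinct exception type so callers (and
the command-line layer) can map failures to stages and exit codes.
"""


class ImlenError(Exception):
    """Base class for all errors raised by this package."""


# --- input / I-O errors -------------------------------------------------

class MeshReadError(ImlenError):
    """The mesh file is missing or cannot be parsed in the stated format."""


class EmptyMeshError(ImlenError):
    """The mesh file parsed but contains no usable geometry."""


class NonFiniteCoordinateError(ImlenError):
    """Mesh or centerline coordinates contain NaN or infinity."""


class MeshValidationError(ImlenError):
    """The mesh violates a structural invariant (too small, bad indices)."""


class CenterlineError(ImlenError):
    """The centerline file is malformed or has fewer than two distinct points."""


class ResultWriteError(ImlenError):
    """An estimator result could not be written to disk."""


# --- computation errors -------------------------------------------------

class OstiumNotFoundError(ImlenError):
    """The centerline never exits the aortic surface (no inside-to-outside
    sign change in the signed-distance sequence)."""


class ProfileError(ImlenError):
    """Too little centerline remains beyond the ostium to build a profile."""


class FitError(ImlenError):
    """The piecewise fit cannot be performed (degenerate design or too few
    samples in the fit window)."""


class PhantomError(ImlenError):
    """A phantom specification is internally inconsistent or unrealizable."""


class CohortParseError(ImlenError):
    """A cohort-table cell cannot be interpreted as an IM length."""


# --- warning categories -------------------------------------------------

class ImlenWarning(UserWarning):
    """Base class for package warnings."""


class DuplicatePointWarning(ImlenWarning):
    """Consecutive duplicate centerline points were dropped."""


class SignConventionWarning(ImlenWarning):
    """The open-surface pseudo-normal sign rule is in use, or a degenerate
    normal forced a positive-sign fallback."""


class OstiumWarning(ImlenWarning):
    """No centerline point lies inside the surface; arc length starts at the
    first centerline point."""


class FitWindowWarning(ImlenWarning):
    """The profile is shorter than the requested fit window, or the fitted
    transition lies beyond the window so the second slope is unsupported."""


class CohortIntegrityWarning(ImlenWarning):
    """The cohort table does not have the expected per-anomaly row counts."""
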