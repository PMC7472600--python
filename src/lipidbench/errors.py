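"""Exception hierarchy.

Every domain precondition failure raises a subclass of :class:`LipidbenchError`
with a short, stable message prefix so callers (and the CLI) can branch on type
rather than parse text.
"""


class LipidbenchError(Exception):
    """Base class for all lipidbench domain errors."""


class SchemaError(LipidbenchError):
    """Malformed input file: bad header, duplicate row, out-of-range value."""


class InsufficientStandardsError(LipidbenchError):
    """Fewer than 3 calibration points, or fewer than 2 distinct levels."""


class NonMonotoneCalibrationError(LipidbenchError):
    """Fitted calibration slope is not positive."""


class UncalibratedPeakError(LipidbenchError):
    """A cluster peak is present in a sample but no curve was supplied."""


class EmptyProfileError(LipidbenchError):
    """All cluster quantities are zero; no composition can be closed."""


class InconsistentAreasError(LipidbenchError):
    """Total chromatogram area smaller than the cluster area."""


class InsufficientCohortError(LipidbenchError):
    """Fewer than 2 non-missing values for a reference interval."""


class SampleTooSmallError(LipidbenchError):
    """Omnibus normality test requested below its validity floor (n < 20)."""


class InsufficientGroupError(LipidbenchError):
    """A comparison group has fewer than 3 observations."""


class DegenerateCorrelationError(LipidbenchError):
    """A correlation input vector is constant."""


class IncompleteMetadataError(LipidbenchError):
    """Cohort metadata does not cover every sample."""


class UndefinedRatioError(LipidbenchError):
    """A ratio denominator is zero. ``ratio_name`` says which ratio."""

    def __init__(self, ratio_name: str):
        self.ratio_name = ratio_name
        super().__init__(f"undefined ratio: {ratio_name}")


class InfeasibleSpecError(LipidbenchError):
    """Synthetic-cohort spec cannot be calibrated (non-positive latent scale)."""
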