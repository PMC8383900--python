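"""Exception hierarchy for the fundus-tessellation toolkit.

Every failure mode that callers are expected to handle has its own class;
all inherit from :class:`FundtessError` so a CLI can catch one type.
"""


class FundtessError(Exception):
    """Base class for all package-specific errors."""


class InvalidImage(FundtessError):
    """Raised when an array is not a valid 8-bit RGB fundus image."""


class InvalidConfig(FundtessError):
    """Raised when a configuration field is outside its documented range."""


class NoROIFound(FundtessError):
    """No candidate region survived the ROI screening steps."""


class EmptyROI(FundtessError):
    """An operation that needs ROI pixels received an all-false ROI mask."""


class MaskShapeMismatch(FundtessError):
    """Two rasters that must share dimensions do not."""


class NonBinaryMask(FundtessError):
    """A mask file contained values other than 0 and 255."""


class NoTrainingData(FundtessError):
    """The segmentation trainer received an empty training set."""


class ModelNotTrained(FundtessError):
    """Inference was requested from a model with no fitted weights."""


class InvalidThreshold(FundtessError):
    """Confidence threshold outside the open interval (0, 1)."""


class UndefinedMetric(FundtessError):
    """A performance metric has a zero denominator; the message names it."""


class DensityUnreachable(FundtessError):
    """The synthetic renderer could not reach the requested density."""


class RefusingOverwrite(FundtessError):
    """Output directory already contains files; refusing to clobber them."""


class CohortTooSmall(FundtessError):
    """Cohort size below the minimum for meaningful moment checks."""


class ConstantPredictor(FundtessError):
    """A regression predictor has no variation."""


class EmptyModel(FundtessError):
    """Stepwise elimination removed every candidate predictor."""


class CalibrationFailed(FundtessError):
    """The correlation-structure solver did not meet its tolerances."""


class NoInput(FundtessError):
    """A batch operation received no readable inputs."""
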