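"""Exception hierarchy shared across the toolkit."""


class BirddogError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BirddogError):
    """A keypoint file could not be parsed; the message names the offending line."""


class AmbiguousRecordError(ParseError):
    """The same (frame, landmark) pair appears more than once in the input."""


class ValidationError(BirddogError):
    """A container or parameter object violates one of its invariants."""


class InsufficientDataError(ValidationError):
    """A required landmark is absent or missing in too many frames."""


class CannotInterpolateError(BirddogError):
    """Fewer than two valid samples survive denoising for some landmark axis."""


class UndefinedAngleError(BirddogError):
    """An angle is undefined in every frame (coincident keypoints)."""


class ZeroVarianceError(ValidationError):
    """A column selected for z-scoring has zero variance."""


class SingularDesignError(ValidationError):
    """The regression design matrix is rank deficient."""
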