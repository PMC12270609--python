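"""Exception hierarchy for the Extended Mooney-Rivlin pipeline."""


class ExtMRError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ExtMRError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class SingularDeformationError(DomainError):
    """The classic Mooney (reduced-stress) transform is singular at lambda = 1."""


class GeometryError(ExtMRError, ValueError):
    """Specimen geometry is missing or invalid for the requested conversion."""


class InsufficientDataError(ExtMRError, ValueError):
    """Too few (distinct) samples for the requested regression."""


class RankDeficiencyError(InsufficientDataError):
    """The regression design matrix is rank deficient."""


class NonpositiveInterceptError(ExtMRError, ValueError):
    """No positive stress-axis intercept exists, so the stiffness B cannot be
    estimated; the curve is unusable under this model."""


class DegenerateVarianceError(ExtMRError, ValueError):
    """R-squared is undefined when every observed value is identical."""


class DuplicateLabelError(ExtMRError, ValueError):
    """Two sites share the same label."""


class SingleRegionError(ExtMRError, ValueError):
    """A regional comparison needs at least two distinct regions."""


class CurveParseError(ExtMRError, ValueError):
    """A curve file could not be parsed into numeric samples."""
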