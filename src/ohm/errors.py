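"""Exception types shared across the package."""


class OhmError(Exception):
    """Base class for all package-specific errors."""


class PairsFormatError(OhmError, ValueError):
    """A pairs file violates the expected dialect (missing column, unknown chromosome...)."""


class OrderingError(OhmError, ValueError):
    """Input records are not sorted as required by the operation."""


class InvalidParameterError(OhmError, ValueError):
    """A parameter is outside its documented domain."""


class UndefinedSeparationError(OhmError, ValueError):
    """Genomic separation requested for a cross-chromosome record."""


class InsufficientDataError(OhmError, ValueError):
    """Too few complete observations to compute the statistic."""


class DegenerateFitError(OhmError, ValueError):
    """Degenerate input (singular covariance, perfectly correlated control...)."""


class UndefinedEstimateError(OhmError, ValueError):
    """An estimator's denominator vanishes on the requested range."""
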