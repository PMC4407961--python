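"""Exception hierarchy shared across the package."""


class CavepairsError(Exception):
    """Base class for all data and model errors raised by this package."""


class InsufficientDataError(CavepairsError):
    """Too few records for the requested computation."""


class DegenerateRegressionError(CavepairsError):
    """Allometric regression is not identifiable (zero predictor variance)."""


class DegenerateRangeError(CavepairsError):
    """Normalization range has zero or negative width."""


class TreeError(CavepairsError):
    """Invalid phylogeny input (missing branch lengths, duplicate tips, ...)."""


class SingularCovarianceError(CavepairsError):
    """Tip covariance matrix is singular; typically duplicated zero-length tips."""
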