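"""Exception hierarchy for the cb1pet pipeline."""


class CB1PetError(Exception):
    """Base class for all cb1pet errors."""


class ConfigurationError(CB1PetError, ValueError):
    """Invalid configuration (negative counts, non-positive SDs, ...)."""


class ValidationError(CB1PetError, ValueError):
    """Input data violate a documented invariant."""


class InsufficientDataError(CB1PetError, ValueError):
    """Too few observations to perform a fit."""


class DegenerateFitError(CB1PetError, ArithmeticError):
    """A fit is numerically degenerate (e.g. singular design, zero slope)."""


class EmptyCompositeError(CB1PetError, ValueError):
    """No valid regional estimates available for a composite score."""


class RankDeficientError(CB1PetError, ValueError):
    """Regression design matrix is rank deficient."""
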