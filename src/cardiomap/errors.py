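"""Exception hierarchy for cardiomap."""


class CardiomapError(Exception):
    """Base class for all cardiomap errors."""


class ConfigurationError(CardiomapError):
    """A parameter, scheme name or threshold set is invalid or mismatched."""


class InvalidReferenceError(CardiomapError):
    """The remote (normal-appearing) reference region is unusable."""


class EmptyMapError(CardiomapError):
    """No accepted mapping points / no valid cells to build a map from."""


class UndefinedStatisticError(CardiomapError):
    """A statistic is undefined on the given input (zero variance, empty regions...)."""


class ConvergenceError(CardiomapError):
    """An iterative fit failed to converge within its iteration cap."""
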