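"""Package-wide exception hierarchy."""


class AmpnetError(Exception):
    """Base class for all errors raised by ampnet."""


class ValidationError(AmpnetError):
    """Invalid input data or contract violation (bad sequence, asymmetric
    matrix, missing abundance, ...)."""


class UndefinedStatisticError(AmpnetError):
    """A statistic cannot be computed on this input (zero variance, empty
    intersection, too few observations)."""
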