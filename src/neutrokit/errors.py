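"""Exception types shared across the package."""


class NeutrokitError(ValueError):
    """Base class for all neutrokit errors."""


class ParameterError(NeutrokitError):
    """A parameter violates its documented constraints."""


class InputError(NeutrokitError):
    """Input data are malformed (wrong shape, non-finite, mismatched ids...)."""


class InsufficientDataError(NeutrokitError):
    """Too few observations to compute the requested statistic."""


class UndefinedMetricError(NeutrokitError):
    """The metric is mathematically undefined for this input."""
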