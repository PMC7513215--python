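"""Exception types shared across the toolkit."""


class SekpcaError(Exception):
    """Base class for all package-specific errors."""


class DegenerateEpochError(SekpcaError, ValueError):
    """An epoch has zero standard deviation, so the match tolerance r collapses to 0."""


class UndefinedEntropyError(SekpcaError, ArithmeticError):
    """No template matches at one of the two lengths: the entropy ratio is 0/0 or log(0)."""


class ConfigurationError(SekpcaError, ValueError):
    """A required estimator, parameter or config entry is missing or invalid."""
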