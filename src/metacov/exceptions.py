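"""Exception types shared across the package."""


class MetacovError(ValueError):
    """Base class for all metacov errors."""


class InvalidParameterError(MetacovError):
    """A model or generator parameter violates its constraints."""


class DegenerateDataError(MetacovError):
    """The data do not identify the requested quantity (e.g. no error trials)."""


class EstimationError(MetacovError):
    """An estimator cannot return a finite value (e.g. hit rate of 1 without correction)."""
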