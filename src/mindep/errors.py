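"""Shared exception types."""


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class SeparationError(RuntimeError):
    """Logistic model could not be estimated because the outcome is
    perfectly (or quasi-perfectly) separated by the predictors."""


class ZeroVarianceError(ValueError):
    """A rank test was requested on data with no variation."""
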