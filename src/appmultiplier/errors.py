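"""Exceptions and warnings shared across the package."""


class EstimationError(ValueError):
    """An estimator or procedure cannot produce a defined result."""


class InfeasibleSpecError(ValueError):
    """A simulation specification violates its invariants."""


class UnreliableEstimateWarning(UserWarning):
    """A result was produced but should not be trusted without scrutiny."""


class PartialSampleWarning(UserWarning):
    """Recruitment chains died before reaching the requested sample size."""
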