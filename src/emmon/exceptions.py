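"""Exception hierarchy for emmon.

All errors raised by the library derive from :class:`EmmonError` so callers
can catch one base class at an API boundary (the CLI does exactly that).
"""


class EmmonError(Exception):
    """Base class for all emmon errors."""


class InvalidRecordError(EmmonError):
    """A case record violates the cohort schema (e.g. no sub-model columns)."""


class TruthRequiredError(EmmonError):
    """An accuracy-type computation was requested but ground truth is absent."""


class PolicyMismatchError(EmmonError):
    """An agreement level is not covered by the threshold policy (K mismatch)."""


class EmptyInputError(EmmonError):
    """An operation received an empty cohort or sub-cohort."""


class UndefinedMetricError(EmmonError):
    """A requested metric is undefined on the given input (e.g. 0/0)."""


class UndefinedAUCError(UndefinedMetricError):
    """Error-detection AUCs need at least one error and one correct case."""


class UnstableMetricError(EmmonError):
    """The bootstrap metric was undefined on more than half of the draws."""

    def __init__(self, message: str, n_undefined: int, n_draws: int):
        super().__init__(message)
        self.n_undefined = n_undefined
        self.n_draws = n_draws


class ClassMissingError(EmmonError):
    """Prevalence-controlled resampling needs both classes present."""


class InvalidParameterError(EmmonError):
    """A numeric parameter is outside its admissible range."""


class SimConfigError(EmmonError):
    """Simulator configuration failed validation; lists offending fields."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid simulator configuration: " + "; ".join(self.problems))
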