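"""Exception types shared across the pipeline."""


class ReadmitError(Exception):
    """Base class for package errors."""


class UndefinedAUCError(ReadmitError):
    """AUC is undefined because only one outcome class is present."""


class ConfigurationError(ReadmitError):
    """Invalid user configuration (windows, cutpoints, parameters)."""


class CohortDataError(ReadmitError):
    """Inconsistent visit data (e.g. overlapping stays for one patient)."""


class InterceptTuningError(ReadmitError):
    """The simulator could not reach the target prevalence."""


class ModelFitError(ReadmitError):
    """A model fit failed (degenerate folds, constant scores, ...)."""
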