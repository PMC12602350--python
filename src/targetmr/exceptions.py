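class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class ConfigurationError(TargetMRError):
    """Invalid configuration: missing columns, bad parameters, mismatched scales."""


class InputError(TargetMRError):
    """Input data unusable: empty after filtering, missing required fields."""


class InstrumentationError(TargetMRError):
    """No instrument could be constructed for a locus at any threshold."""


class MethodUnavailableError(TargetMRError):
    """An estimator's preconditions (e.g. minimum SNP count) are not met."""


class UndefinedRatioError(TargetMRError):
    """Wald ratio undefined because the exposure effect is exactly zero."""


class DomainError(TargetMRError, ValueError):
    """Argument outside its mathematical domain."""
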