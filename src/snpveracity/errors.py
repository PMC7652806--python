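"""Exception and warning types shared across the package."""


class SnpVeracityError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(SnpVeracityError):
    """A VCF record violates its own contract (e.g. genotype index outside the allele list)."""


class ContractViolationError(SnpVeracityError):
    """Caller passed arguments violating a documented precondition."""


class EmptyIntersectionError(SnpVeracityError):
    """No genomic positions are shared between the VCF and the array table."""


class ConfigError(SnpVeracityError):
    """Invalid configuration (network shape, strategy parameters, ...)."""


class EncodingError(SnpVeracityError):
    """A matrix does not match the encoding a model was trained with."""


class UndefinedMetricError(SnpVeracityError):
    """A classification metric is undefined for the given counts (empty class)."""


class UndefinedWeightError(SnpVeracityError):
    """Class weights requested with an empty class."""


class TrainingError(SnpVeracityError):
    """Training diverged (non-finite loss) or could not proceed."""


class DegenerateFeatureWarning(UserWarning):
    """A feature was dropped (zero variance or excessive missingness)."""


class ConfigWarning(UserWarning):
    """A configuration is usable but statistically degenerate (e.g. infeasible truncation)."""
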