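"""Exception and warning types shared across the package."""


class LitqueryError(Exception):
    """Base class for all package errors."""


class MalformedStoreError(LitqueryError):
    """A variant table or store layout violates the store contract."""


class SchemaMismatchError(LitqueryError):
    """A row carries annotation columns not expressible in the target schema."""


class AmbiguousAnalysisError(LitqueryError):
    """Two analysis files for one sample cannot be ordered (hard timestamp tie)."""


class ConfigError(LitqueryError):
    """An invalid configuration value (unknown AF source, bad threshold, ...)."""


class AlertValidationError(LitqueryError):
    """A gene-alert record violates the alert contract."""


class UnknownCriterionError(LitqueryError):
    """An evidence-code token is not a recognised ACMG-AMP criterion."""


class MetricError(LitqueryError):
    """A summary metric is undefined for the given inputs (zero denominator)."""


class ParseWarning(UserWarning):
    """A cell could not be parsed; its value was set to missing."""
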