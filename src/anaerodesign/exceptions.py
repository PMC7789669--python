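"""Package-level exception hierarchy."""


class AnaerodesignError(Exception):
    """Base class for all package errors."""


class ConfigError(AnaerodesignError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(AnaerodesignError, ValueError):
    """Malformed input table; the message carries the line number."""


class LabelError(AnaerodesignError, KeyError):
    """A strain or class label is missing or inconsistent."""


class NormalizationError(AnaerodesignError, ValueError):
    """Size-factor estimation impossible (no gene nonzero in all samples)."""


class ModelValidationError(AnaerodesignError, ValueError):
    """A metabolic model violates its structural invariants."""


class PreconditionError(AnaerodesignError, ValueError):
    """An operation was called outside its stated precondition."""
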