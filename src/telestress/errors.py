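"""Exception hierarchy for the telestress pipeline."""


class TelestressError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TelestressError):
    """A record or value violates a domain invariant."""


class FormatError(TelestressError):
    """A file does not match the expected CSV dialect."""


class ConfigurationError(TelestressError):
    """A registry/spec/config references something unknown or inconsistent."""


class UndefinedRateError(TelestressError):
    """Teleworking rate undefined (participant never worked)."""


class DegenerateTrainingError(TelestressError):
    """Training set contains a single class; no classifier can be fit."""


class SchemaError(TelestressError):
    """Feature names at prediction time do not match the training schema."""


class MissingInputError(TelestressError):
    """A pipeline stage is missing an input artifact from an earlier stage."""
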