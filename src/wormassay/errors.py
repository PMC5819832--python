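"""Exception hierarchy used across the package."""


class WormAssayError(Exception):
    """Base class for all package errors."""


class SchemaError(WormAssayError):
    """A required column or field is missing from an input table."""


class ValidationError(WormAssayError):
    """A value violates a domain invariant (e.g. more dauers than animals)."""


class EmptyInputError(WormAssayError):
    """An input table contains no data rows."""


class ConfigError(WormAssayError):
    """A configuration value is out of range or inconsistent."""


class InsufficientReplicationError(WormAssayError):
    """A statistical procedure was asked to run with too few replicates."""


class NotNestedError(WormAssayError):
    """Likelihood-ratio test requested for models that are not nested."""
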