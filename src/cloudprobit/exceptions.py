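"""Exception hierarchy for cloudprobit."""


class CloudprobitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CloudprobitError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataError(CloudprobitError):
    """Input data violate a structural contract (schema, referential integrity)."""
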