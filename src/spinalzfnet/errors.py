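"""Exception types shared across the pipeline."""


class SpinalZFNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(SpinalZFNetError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(ConfigurationError):
    """A feature schema does not match the one a model was trained on."""
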