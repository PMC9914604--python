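"""Exception types shared across the pipeline."""


class PulsebeatError(Exception):
    """Base class for all package errors."""


class InputError(PulsebeatError):
    """A source file, frame, or argument violates an input contract."""


class ConfigurationError(PulsebeatError):
    """A configuration value is missing, unknown, or inconsistent."""
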