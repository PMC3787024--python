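"""Exception types shared across the package."""


class SerialPulseError(Exception):
    """Base class for package errors."""


class ValidationError(SerialPulseError, ValueError):
    """Invalid parameter values or malformed input data."""


class ConfigError(SerialPulseError, ValueError):
    """Bad run configuration: unknown keys, unknown treatment groups, ..."""


class NumericalError(SerialPulseError, RuntimeError):
    """Integrator failure or non-finite state during simulation."""
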