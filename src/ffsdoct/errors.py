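"""Exception types shared across the toolkit."""


class InvalidParameterError(ValueError):
    """A physical or numerical parameter violates its contract."""


class ConfigurationError(RuntimeError):
    """A configuration file or calibration object is missing or inconsistent."""
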