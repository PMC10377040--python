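"""Exception types shared across the package."""


class AbdynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AbdynError):
    """A configuration value is inconsistent or invalid (e.g. a
    non-decade-spaced affinity ladder, or an unknown config key)."""


class IntegrationError(AbdynError):
    """The ODE solver failed (step-size underflow, non-finite state, or a
    negative undershoot beyond the tolerance band).

    Attributes
    ----------
    last_valid_time : float or None
        The last time the solver reached before failing, when known.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time
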