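"""Exception types shared across the package."""


class ShearscapeError(Exception):
    """Base class for package-specific failures."""


class CalibrationError(ShearscapeError):
    """The requested mean fragment size cannot be reached by any critical length."""


class InsufficientDataError(ShearscapeError):
    """Too few observations to compute the requested statistic."""


class ConfigurationError(ShearscapeError):
    """An operation was invoked on inputs missing a required component."""
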