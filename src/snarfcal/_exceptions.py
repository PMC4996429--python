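"""Exception hierarchy shared across the package."""


class SnarfCalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SnarfCalError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(SnarfCalError, ValueError):
    """A delimited-text input could not be parsed; names the offending line."""


class RatioRangeError(SnarfCalError, ValueError):
    """A measured ratio lies outside the open interval between the
    calibration's limiting ratios, so no pH maps to it."""


class ConfigError(SnarfCalError, ValueError):
    """A synthetic-data configuration is internally inconsistent."""


class FitError(SnarfCalError, RuntimeError):
    """Nonlinear least-squares calibration failed or was refused."""


class NoEndpointError(FitError):
    """Titration lacks a visible end-point in the coordinate being fitted,
    so fixed-plateau ratio fitting is refused."""
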