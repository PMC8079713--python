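"""Exception types shared across the package."""


class VerciniError(Exception):
    """Base class for package errors."""


class ParameterError(VerciniError, ValueError):
    """A physical parameter is outside its valid domain."""


class ConfigError(VerciniError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class NoRingDetectedError(VerciniError):
    """Ring fit succeeded numerically but no annulus signal rises above noise."""


class FitError(VerciniError):
    """A model fit cannot be set up (degenerate or insufficient data)."""
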