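"""Exception hierarchy shared by all pipeline stages."""


class VenomicsError(Exception):
    """Base class for all package errors."""


class FormatError(VenomicsError, ValueError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(VenomicsError, ValueError):
    """Parsed or computed data violate a stage invariant."""


class ConfigurationError(VenomicsError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class FitError(VenomicsError, ValueError):
    """A model fit is degenerate (e.g. all points identical)."""
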