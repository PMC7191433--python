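"""Exception hierarchy shared across the pipeline stages."""


class GlycoxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlycoxError):
    """An invalid configuration value; the message names the offending field."""


class DataError(GlycoxError):
    """Input data violate a precondition (empty window, duplicate ids, ...)."""


class IdentifiabilityError(GlycoxError):
    """The requested variance components cannot be identified from the data."""


class FitError(GlycoxError):
    """A model fit failed to converge; carries diagnostics where available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
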