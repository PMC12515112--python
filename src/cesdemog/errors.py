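"""Exception hierarchy shared across the pipeline stages."""


class CesdemogError(Exception):
    """Base class for all package errors."""


class SchemaError(CesdemogError):
    """A capture table is missing required columns."""


class DataError(CesdemogError):
    """Input data violate a precondition (too few years, no recaptures, ...)."""


class ConfigError(CesdemogError):
    """A simulation or pipeline configuration is invalid."""


class ConvergenceError(CesdemogError):
    """An optimizer failed to converge from every starting point."""
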