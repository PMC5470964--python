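"""Exception hierarchy shared across the pipeline."""


class RtsigError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RtsigError, ValueError):
    """An input table violates its declared schema (duplicates, bad enum tokens, ...)."""


class ParseError(RtsigError, ValueError):
    """A cell could not be parsed; the message names the offending row/column."""


class ValidationError(RtsigError, ValueError):
    """A computed or supplied object violates an invariant."""


class ConfigError(RtsigError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""
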