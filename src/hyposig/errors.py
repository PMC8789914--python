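"""Exception hierarchy. Parsers reject malformed input rather than coerce it."""


class HyposigError(Exception):
    """Base class for all package errors."""


class ConfigError(HyposigError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParseError(HyposigError, ValueError):
    """Malformed external file; message names file, line and field."""


class SchemaError(HyposigError, ValueError):
    """Structurally valid file violating a documented column contract."""


class AnalysisError(HyposigError, ValueError):
    """Degenerate analysis input (empty class, missing condition, ...)."""
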