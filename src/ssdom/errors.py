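"""Exception hierarchy shared across the pipeline."""


class SSDomError(Exception):
    """Base class for all pipeline errors."""


class ParseError(SSDomError, ValueError):
    """A file could not be parsed (malformed cell, unknown token, ...)."""


class ValidationError(SSDomError, ValueError):
    """A parsed object violates an invariant (duplicate ids, negative counts, ...)."""


class DesignError(SSDomError, ValueError):
    """The sample design is incomplete or inconsistent with the count matrix."""


class ConfigError(SSDomError, ValueError):
    """A configuration object is internally inconsistent."""
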