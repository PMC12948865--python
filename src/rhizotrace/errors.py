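"""Exception hierarchy shared across the pipeline stages."""


class RhizotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidIsotopeRatioError(RhizotraceError, ValueError):
    """A delta value or atom fraction lies outside its physical domain."""


class DegenerateMixingError(RhizotraceError, ZeroDivisionError):
    """Two-pool mixing endmembers coincide; the mixing fraction is undefined."""


class UndefinedPartitionError(RhizotraceError, ValueError):
    """Both excess masses of a tracer partition are zero (or the percent is singular)."""


class IncompleteDesignError(RhizotraceError, ValueError):
    """A sampling position expected by the design is missing."""


class ConfigurationError(RhizotraceError, ValueError):
    """Run or simulation configuration is inconsistent (geometry, fractions, paths)."""


class SchemaError(RhizotraceError, ValueError):
    """An input table violates its documented schema."""


class ReferencePairingError(RhizotraceError, ValueError):
    """A labelled measurement has no matching natural-abundance reference."""


class MissingGroupError(RhizotraceError, ValueError):
    """A treatment group required by a summary is empty."""
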