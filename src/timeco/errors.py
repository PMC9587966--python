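"""Exception types shared across the package."""


class TimecoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TimecoError, ValueError):
    """An input file violates its expected format or schema."""


class ValidationError(TimecoError, ValueError):
    """An in-memory object violates a domain invariant."""


class UndefinedMetricError(TimecoError, ValueError):
    """A metric is mathematically undefined for the given input
    (e.g. diversity of an empty repertoire)."""
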