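"""Exception hierarchy for posturekit.

All exceptions derive from :class:`PostureKitError` (itself a ``ValueError``)
so callers can catch everything from this package with one clause while
standard-library semantics are preserved.
"""


class PostureKitError(ValueError):
    """Base class for all posturekit errors."""


class SkeletonParseError(PostureKitError):
    """A skeleton CSV file is malformed (bad row, bad header)."""


class SchemaError(PostureKitError):
    """Columns / dimensions do not match the expected layout."""


class OrderingError(PostureKitError):
    """Timestamps or frame indices are not strictly increasing."""


class ConfigError(PostureKitError):
    """Invalid configuration value (non-positive rate, unknown id, ...)."""


class DegenerateGeometryError(PostureKitError):
    """A body segment has zero length, so no direction is defined."""


class SentinelFrameError(PostureKitError):
    """A geometric operation was applied to a sentinel (missing) frame."""


class EvaluationError(PostureKitError):
    """A fitness or metric evaluation produced an unusable result."""
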