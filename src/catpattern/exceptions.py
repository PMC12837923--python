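"""Exception hierarchy.

All package errors derive from :class:`CatPatternError` so callers can catch
one base class at pipeline boundaries.
"""


class CatPatternError(Exception):
    """Base class for all catpattern errors."""


class SchemaError(CatPatternError):
    """A file or table is structurally malformed (e.g. missing columns)."""


class IntegrityError(CatPatternError):
    """Structurally valid data violate a content invariant (bad labels,
    duplicate trial keys, impossible trial multiplicities)."""


class AlignmentError(CatPatternError):
    """Two sequences or tables that must share a stimulus/category frame
    do not."""


class ConfigurationError(CatPatternError):
    """A generator or analysis specification is internally inconsistent."""
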