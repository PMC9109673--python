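"""Exception hierarchy for the themesort pipeline.

The CLI maps these onto distinct exit codes (config 2, parse 3,
computation 4), so every stage raises a subclass of ThemesortError
rather than a bare ValueError.
"""


class ThemesortError(Exception):
    """Base class for all package errors."""


class ConfigError(ThemesortError):
    """Invalid parameter or configuration value."""


class FormatError(ThemesortError):
    """A file does not conform to the expected tabular format."""


class ParseError(FormatError):
    """A field could not be parsed (e.g. non-integer quote id)."""


class DuplicateAssignmentError(FormatError):
    """The same (quote, rater) pair appears with conflicting groups."""


class CoverageError(ThemesortError):
    """A partition does not cover the required item set."""


class ReferenceError_(ThemesortError):
    """A refinement action references an unknown quote or theme."""


class SizeError(ThemesortError):
    """An instance is too large for an exact (enumerative) routine."""


class EmptyOverlapError(ThemesortError):
    """Two partitions share no commonly covered quotes."""


class LayoutError(ThemesortError):
    """Layout requested for an empty network."""
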