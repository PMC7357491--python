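"""Exception hierarchy for rhizorank.

All errors derive from :class:`RhizorankError` so callers can catch the
package's failures with one clause; most also derive from the matching
builtin (``ValueError``/``KeyError``) so generic handling keeps working.
"""


class RhizorankError(Exception):
    """Base class for all rhizorank errors."""


class SchemaError(RhizorankError, ValueError):
    """An input table is missing required columns or has a bad header."""


class IntegrityError(RhizorankError, ValueError):
    """Duplicate keys or inconsistent identifiers in a table."""


class ParseError(RhizorankError, ValueError):
    """A cell could not be parsed as the expected type."""


class DomainError(RhizorankError, ValueError):
    """A value lies outside the mathematically valid domain."""


class DesignError(RhizorankError, ValueError):
    """A model design is degenerate (too few levels, groups, or observations)."""


class SingularDesignError(DesignError):
    """The design matrix is rank deficient."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class CompletenessError(RhizorankError, ValueError):
    """A required estimate, attribute, or cell is missing."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ConfigError(RhizorankError, ValueError):
    """An attribute/scenario/synthetic configuration is invalid."""
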