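"""Exception hierarchy for corrpath.

All corrpath-raised errors derive from :class:`CorrpathError` so callers can
catch the package's failures in one clause while still discriminating the
cause.  Parsing/validation errors carry enough context (column name, row
number, offending edge) to point at the defective input line.
"""


class CorrpathError(Exception):
    """Base class for all corrpath errors."""


class SchemaError(CorrpathError):
    """A required column is missing or cannot be resolved."""


class ParseError(CorrpathError):
    """A cell could not be parsed; the message cites the row."""


class IntegrityError(CorrpathError):
    """Duplicate keys or inconsistent metadata within a dataset."""


class MapValidationError(CorrpathError):
    """A pathway map violates its structural invariants."""


class InputError(CorrpathError):
    """An operation received arguments outside its contract."""


class LookupError_(CorrpathError):
    """A requested entity or condition is not present."""
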