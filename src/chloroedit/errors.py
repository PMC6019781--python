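"""Exception hierarchy shared across the package."""


class ChloroeditError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChloroeditError):
    """A structured input file does not match the documented layout."""


class ParseError(FormatError):
    """A field could not be converted to its expected type."""


class DuplicateEntryError(FormatError):
    """A keyed table repeats a key that must be unique."""


class InputError(ChloroeditError):
    """An argument violates a documented precondition."""


class NoCoverageError(InputError):
    """An editing fraction was requested at a site with zero informative reads."""


class ConsistencyError(ChloroeditError):
    """Two inputs that must agree (e.g. pileup vs genome) disagree."""


class DegenerateSpreadError(ChloroeditError):
    """A z-score was requested for a score population with zero variance."""


class CoordinateError(ChloroeditError):
    """Annotation coordinate arithmetic produced an inconsistent interval."""


class CollisionError(InputError):
    """A planted feature overlaps a previously planted one or the sequence bounds."""


class ConfigError(ChloroeditError):
    """A configuration combination is contradictory."""
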