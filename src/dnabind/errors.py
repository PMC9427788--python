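"""Exception hierarchy for dnabind.

Every error raised by the library derives from :class:`DnabindError`, so
callers (and the CLI) can catch one base class. Subclasses distinguish
schema problems, unparseable cells, violated numeric domains, and
datasets too small or too degenerate to analyse.
"""


class DnabindError(Exception):
    """Base class for all dnabind errors."""


class DataFormatError(DnabindError):
    """A file or table does not have the expected columns/layout."""


class DataParseError(DnabindError):
    """A cell could not be converted to the expected type."""


class InsufficientDataError(DnabindError):
    """Too few usable points for the requested analysis."""


class DomainError(DnabindError, ValueError):
    """A numeric argument lies outside its physical domain."""


class MissingReferenceError(DnabindError):
    """A required reference point (zero-ligand, zero-salt, ...) is absent."""


class AlignmentError(DnabindError):
    """Two spectra do not share a common grid."""


class NoBindingSignalError(DnabindError):
    """The fitted line is degenerate (zero slope): no binding signal."""


class ConvergenceError(DnabindError):
    """An iterative solver failed to reach its tolerance."""
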