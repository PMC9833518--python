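"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`OverrepError`,
so the CLI can catch one type and print a one-line diagnostic.
"""


class OverrepError(Exception):
    """Base class for all overrep errors."""


class InvalidIdentifierError(OverrepError):
    """A gene label that cannot be normalized (empty, whitespace-only,
    or containing internal whitespace)."""


class GmtFormatError(OverrepError):
    """Malformed GMT content (short line, duplicate set name, empty file)."""


class QueryFormatError(OverrepError):
    """Malformed query input (bad CSV row shape)."""


class EmptyQueryError(OverrepError):
    """A query list that is empty after parsing or background filtering."""


class SubsetViolationError(OverrepError):
    """Strict-mode assembly found query genes missing from the background."""


class ParameterError(OverrepError):
    """Numeric parameters violating an invariant (named in the message)."""


class DegenerateBackgroundError(OverrepError):
    """INTERSECT background resolution left an empty effective background
    or query; the dataset should be skipped, not crash the run."""


class NoResultsError(OverrepError):
    """No testable (query x gene set) pair remained; advises USER mode."""


class UnknownQueryError(OverrepError):
    """A query name absent from the supplied results."""


class UnknownFormatError(OverrepError):
    """An unsupported export format name."""
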