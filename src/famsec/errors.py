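"""Exception hierarchy shared across the toolkit.

All toolkit errors derive from :class:`FamsecError` so callers can catch one
type; the subclasses distinguish malformed input text (:class:`ParseError`),
internally inconsistent data (:class:`IntegrityError`), misuse of an API or
CLI (:class:`UsageError`), and references to labels or fragments that do not
exist (:class:`ResolutionError`).
"""


class FamsecError(Exception):
    """Base class for all toolkit errors."""


class ParseError(FamsecError):
    """Input text could not be parsed; the message names the line/section."""


class IntegrityError(FamsecError):
    """Data is self-inconsistent (conflicting duplicates, mixed temperatures...)."""


class UsageError(FamsecError):
    """An operation was invoked with invalid arguments."""


class ResolutionError(UsageError):
    """A referenced atom label, fragment, or step does not exist."""


class DegenerateGeometryError(UsageError):
    """A geometric quantity is undefined for the given coordinates."""
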