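"""Exception hierarchy for hrtwin.

All errors raised by the library derive from :class:`HrtwinError` so callers
(and the CLI) can catch one base class.
"""


class HrtwinError(Exception):
    """Base class for all hrtwin errors."""


class WindowTooShortError(HrtwinError, ValueError):
    """The fit window end k violates the reliability constraint k >= 2m+1."""


class SeriesTooShortError(HrtwinError, ValueError):
    """The series is too short to produce at least one fit and one prediction."""


class InsufficientHistoryError(HrtwinError, ValueError):
    """Fewer recent observations supplied than the model order requires."""


class NonFiniteDesignError(HrtwinError, ValueError):
    """A lag design contains NaN or infinite entries."""


class InvalidSpecError(HrtwinError, ValueError):
    """A synthetic-series specification violates its invariants."""


class DuplicateParticipantError(HrtwinError, ValueError):
    """Two summaries or record groups share a participant id."""


class GapError(HrtwinError, ValueError):
    """A participant's minute index has a gap under the strict gap policy."""


class TableParseError(HrtwinError, ValueError):
    """A heart-rate table could not be parsed."""


class ConfigError(HrtwinError, ValueError):
    """A run configuration value violates its invariants."""
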