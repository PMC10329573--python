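"""Exception hierarchy for the uroscreen pipeline."""


class UroscreenError(Exception):
    """Base class for all package errors."""


class InputError(UroscreenError):
    """A value violates an operation's preconditions (negative count, bad months, ...)."""


class FormatError(UroscreenError):
    """A file does not conform to the documented dialect (missing header, decimal comma, ...)."""


class RuleSyntaxError(UroscreenError):
    """A screening-rule expression failed to parse.

    Carries ``position`` (0-based character offset) when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class AdjudicationError(UroscreenError):
    """A culture cannot be adjudicated (unknown organism with no fallback class)."""


class InfeasibleSpecError(UroscreenError):
    """A cohort spec stratum has an empty admissible attribute region.

    Names the offending stratum in the message.
    """


class UnknownOrganismWarning(UserWarning):
    """Emitted when a species name is not found in the organism catalog."""
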