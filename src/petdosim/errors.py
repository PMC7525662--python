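"""Exception hierarchy for validation and pipeline failures."""


class DosimetryError(Exception):
    """Base class for all petdosim errors."""


class ValidationError(DosimetryError, ValueError):
    """A domain object violates one of its invariants."""


class FrameScheduleError(ValidationError):
    """Frames are unordered, overlapping, or inconsistent across curves."""


class MissingOrganError(ValidationError, KeyError):
    """An organ required by an operation is absent from its input table."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class UnknownOrganError(ValidationError):
    """An organ label is outside the controlled vocabulary."""


class NegativeRemainderError(ValidationError):
    """Source-organ residence times exceed the whole-body residence time
    by more than the allowed tolerance."""
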