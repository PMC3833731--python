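"""Exception hierarchy shared across the package."""

from __future__ import annotations


class KaryoError(Exception):
    """Base class for all domain errors raised by this package."""


class BandParseError(KaryoError, ValueError):
    """A Keyl-notation token or band label could not be parsed.

    Carries the offending token and its position in the input string.
    """

    def __init__(self, message: str, token: str | None = None, position: int | None = None):
        super().__init__(message)
        self.token = token
        self.position = position


class ValidationError(KaryoError, ValueError):
    """One or more invariants failed.  ``problems`` lists every failure."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class IncomparableArmsError(KaryoError, ValueError):
    """Two arm sequences cannot be compared (different band sets or unmapped)."""
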