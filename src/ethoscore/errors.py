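"""Exception hierarchy for ethoscore.

All library errors derive from :class:`EthoscoreError` so callers can catch
one base class at the CLI boundary.
"""


class EthoscoreError(Exception):
    """Base class for all ethoscore errors."""


class EthogramError(EthoscoreError):
    """Invalid ethogram definition (duplicate keys/names, bad color, ...)."""


class UnsupportedTemplateError(EthogramError):
    """Requested built-in template does not exist."""


class TimelineError(EthoscoreError):
    """Invalid keystroke log or scored-trial structure."""


class UnknownKeyError(TimelineError):
    """A keystroke does not map to any behavior of the governing ethogram."""

    def __init__(self, key: str, t: float):
        self.key = key
        self.t = t
        super().__init__(f"unknown key {key!r} at t={t:g} s")


class EventOutOfRangeError(TimelineError):
    """An event timestamp lies outside the trial duration."""


class UnsortedEventsError(TimelineError):
    """Keystroke events are not ordered by time."""


class RangeError(EthoscoreError):
    """A time window or bin width is outside the valid range."""


class SchemaMismatchError(EthoscoreError):
    """Trial and ethogram (or model and ethogram) disagree on behaviors."""


class StyleError(EthoscoreError):
    """Degenerate visual-map style (e.g. zero-width bar)."""


class AgreementError(EthoscoreError):
    """Invalid input to a rater-agreement computation."""


class InsufficientDataError(AgreementError):
    """Fewer than three paired observations for a correlation."""


class ProjectError(EthoscoreError):
    """Project store violation (duplicates, missing references)."""


class ConflictError(ProjectError):
    """A trial with the same (subject, test, session, trial, rater) exists."""


class ReferentialError(ProjectError):
    """Reference to an unregistered subject, group, or ethogram."""
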