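"""Keystroke logs to validated bout timelines.

Conventions
-----------
* All bouts are half-open intervals ``[start, end)``; a transition instant
  belongs to the new behavior, so adjacent bouts partition time with no
  double counting.
* Toggle semantics: a state-behavior keystroke at time ``t`` closes the
  open bout (if any) at ``t`` and opens a bout of that behavior; the last
  open bout closes at the trial duration.  Time before the first state
  keystroke is an unscored gap.  Point-behavior keystrokes insert an
  occurrence without disturbing the open bout.  Pressing the key of the
  currently open behavior is a no-op.  Two state keystrokes at the same
  instant produce a zero-length bout, which is dropped — the later
  keystroke wins.
* Events with ``t`` beyond the trial duration are rejected, not clamped.

Keystroke log file format: UTF-8 text, one event per line,
``<t_seconds><TAB><key>``; ``#`` starts a comment; decimal point is ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EventOutOfRangeError,
    RangeError,
    TimelineError,
    UnknownKeyError,
    UnsortedEventsError,
)
from .ethogram import Ethogram

__all__ = [
    "KeyEvent",
    "Bout",
    "PointOccurrence",
    "ScoredTrial",
    "keystrokes_to_timeline",
    "slice_segment",
    "coverage",
    "read_keylog",
    "write_keylog",
    "state_labels",
    "GAP_LABEL",
]

#: label used for unscored time when sampling a timeline
GAP_LABEL = "gap"


@dataclass(frozen=True)
class KeyEvent:
    """One timestamped keystroke (seconds from trial start)."""

    t: float
    key: str

    def __post_init__(self) -> None:
        if self.t < 0:
            raise TimelineError(f"event time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class Bout:
    """One contiguous episode of a state behavior, the interval [start, end)."""

    behavior: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise TimelineError(
                f"bout {self.behavior!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PointOccurrence:
    """One instantaneous occurrence of a point behavior."""

    behavior: str
    t: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise TimelineError(f"point occurrence time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class ScoredTrial:
    """One animal x one trial: ordered disjoint bouts plus point occurrences."""

    subject_id: str
    duration_s: float
    bouts: tuple[Bout, ...] = ()
    points: tuple[PointOccurrence, ...] = ()
    session_index: int = 1
    trial_index: int = 1
    rater_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(self.bouts))
        object.__setattr__(self, "points", tuple(self.points))
        self._validate()

    def _validate(self) -> None:
        if not self.duration_s > 0:
            raise TimelineError("duration_s must be > 0")
        if self.session_index < 1 or self.trial_index < 1:
            raise TimelineError("session_index and trial_index must be >= 1")
        prev_end = 0.0
        for b in self.bouts:
            if b.start < prev_end - 1e-12:
                raise TimelineError(
                    f"bouts overlap or are unsorted near t={b.start:g} ({b.behavior})"
                )
            if b.end > self.duration_s + 1e-9:
                raise TimelineError(
                    f"bout [{b.start:g}, {b.end:g}) exceeds trial duration {self.duration_s:g}"
                )
            prev_end = b.end
        for p in self.points:
            if not (0 <= p.t <= self.duration_s):
                raise TimelineError(
                    f"point occurrence at t={p.t:g} outside [0, {self.duration_s:g}]"
                )

    @property
    def total_bout_time(self) -> float:
        return float(sum(b.duration for b in self.bouts))

    def behavior_names(self) -> set[str]:
        return {b.behavior for b in self.bouts} | {p.behavior for p in self.points}


def keystrokes_to_timeline(
    events: Sequence[KeyEvent],
    etho: Ethogram,
    duration_s: float,
    *,
    subject_id: str = "",
    session_index: int = 1,
    trial_index: int = 1,
    rater_id: str = "",
    skip_unknown: bool = False,
) -> ScoredTrial:
    """Convert an ordered keystroke log into a validated :class:`ScoredTrial`.

    Parameters
    ----------
    events : sequence of KeyEvent
        Sorted by time; ties keep input order.
    etho : Ethogram
        Supplies the key -> behavior mapping.
    duration_s : float
        Trial duration; every event must satisfy ``t <= duration_s``.
    skip_unknown : bool
        If True, events whose key is not in the ethogram are dropped
        (collected on the returned trial is not needed; they are simply
        ignored).  If False, an :class:`UnknownKeyError` is raised.
    """
    if not duration_s > 0:
        raise TimelineError("duration_s must be > 0")
    key_map = etho.key_map

    bouts: list[Bout] = []
    points: list[PointOccurrence] = []
    open_behavior: str | None = None
    open_start = 0.0
    prev_t = -np.inf

    for ev in events:
        if ev.t < prev_t:
            raise UnsortedEventsError(
                f"events out of order: t={ev.t:g} after t={prev_t:g}"
            )
        prev_t = ev.t
        if ev.t > duration_s:
            raise EventOutOfRangeError(
                f"event at t={ev.t:g} exceeds trial duration {duration_s:g}"
            )
        beh = key_map.get(ev.key)
        if beh is None:
            if skip_unknown:
                continue
            raise UnknownKeyError(ev.key, ev.t)
        if beh.kind == "point":
            points.append(PointOccurrence(beh.name, ev.t))
            continue
        # state keystroke
        if beh.name == open_behavior:
            continue  # no-op: repeated key of the open behavior
        if open_behavior is not None and ev.t > open_start:
            bouts.append(Bout(open_behavior, open_start, ev.t))
        # zero-length bout (ev.t == open_start) is dropped: later key wins
        open_behavior = beh.name
        open_start = ev.t

    if open_behavior is not None and duration_s > open_start:
        bouts.append(Bout(open_behavior, open_start, duration_s))

    return ScoredTrial(
        subject_id=subject_id,
        duration_s=float(duration_s),
        bouts=tuple(bouts),
        points=tuple(points),
        session_index=session_index,
        trial_index=trial_index,
        rater_id=rater_id,
    )


def slice_segment(trial: ScoredTrial, a: float, b: float) -> ScoredTrial:
    """Restrict a trial to the window ``[a, b)`` and rebase it to start at 0.

    Bouts are intersected with the window; point occurrences with
    ``a <= t < b`` are kept.  The original trial is unmodified.
    """
    if not (0 <= a < b <= trial.duration_s + 1e-9):
        raise RangeError(
            f"window [{a:g}, {b:g}) outside [0, {trial.duration_s:g}] or empty"
        )
    bouts = []
    for bo in trial.bouts:
        s = max(bo.start, a)
        e = min(bo.end, b)
        if e > s:
            bouts.append(Bout(bo.behavior, s - a, e - a))
    points = [
        PointOccurrence(p.behavior, p.t - a) for p in trial.points if a <= p.t < b
    ]
    return replace(
        trial, duration_s=b - a, bouts=tuple(bouts), points=tuple(points)
    )


def coverage(trial: ScoredTrial) -> float:
    """Fraction of the trial covered by state bouts, in [0, 1]."""
    return trial.total_bout_time / trial.duration_s


def state_labels(trial: ScoredTrial, times: np.ndarray) -> np.ndarray:
    """Label each time in ``times`` with the state behavior active there.

    Unscored instants get :data:`GAP_LABEL`.  Vectorized; used by the
    concordance audit and the visual map renderer's tests.
    """
    times = np.asarray(times, dtype=float)
    labels = np.full(times.shape, GAP_LABEL, dtype=object)
    if not trial.bouts:
        return labels
    starts = np.array([b.start for b in trial.bouts])
    ends = np.array([b.end for b in trial.bouts])
    names = np.array([b.behavior for b in trial.bouts], dtype=object)
    idx = np.searchsorted(starts, times, side="right") - 1
    valid = (idx >= 0) & (times < ends[np.clip(idx, 0, len(ends) - 1)])
    labels[valid] = names[idx[valid]]
    return labels


# ---------------------------------------------------------------------------
# keystroke log file I/O
# ---------------------------------------------------------------------------

def read_keylog(path) -> list[KeyEvent]:
    """Read a keystroke log file (``<t><TAB><key>`` per line, ``#`` comments)."""
    events: list[KeyEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TimelineError(
                    f"{path}:{lineno}: expected '<t><TAB><key>', got {raw!r}"
                )
            t_str, key = parts
            try:
                t = float(t_str)
            except ValueError:
                raise TimelineError(
                    f"{path}:{lineno}: bad timestamp {t_str!r}"
                ) from None
            if len(key) != 1:
                raise TimelineError(
                    f"{path}:{lineno}: key must be a single character, got {key!r}"
                )
            events.append(KeyEvent(t, key))
    return events


def write_keylog(events: Iterable[KeyEvent], path) -> None:
    """Write events in the keystroke log file format."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(f"{ev.t:g}\t{ev.key}\n")
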