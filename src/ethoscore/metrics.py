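"""Per-behavior measures and test-specific indices.

``summarize_trial`` produces, for every behavior of the governing ethogram,
total time, bout/occurrence count, and latency to first bout/occurrence.
Latency is censored at trial duration (with an explicit flag) when the
behavior never occurs, which keeps numeric exports rectangular.

Test-specific indices are populated automatically from the ethogram's
``test_name``:

* EPM: ``pct_open_time = 100 * open / (open + closed)`` and the analogous
  entry percentage.  Center time is excluded from the denominator (a
  documented, switchable convention).
* NOR: discrimination index ``DI = (T_novel - T_fam) / (T_novel + T_fam)``
  and preference index ``PI = 100 * T_novel / (T_novel + T_fam)``; the
  identity ``PI = 50 * (DI + 1)`` holds exactly.

Undefined indices (zero denominators) are reported as ``None``, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import RangeError, SchemaMismatchError
from .ethogram import Ethogram
from .timeline import ScoredTrial, slice_segment

__all__ = [
    "BehaviorMeasure",
    "MeasureSet",
    "summarize_trial",
    "epm_measures",
    "nor_indices",
    "segment_summaries",
]


@dataclass(frozen=True)
class BehaviorMeasure:
    """Totals, counts, and latency for one behavior in one trial."""

    behavior: str
    total_s: float
    count: int
    latency_s: float
    latency_censored: bool


@dataclass(frozen=True)
class MeasureSet:
    """All per-behavior measures plus test-specific indices for one trial."""

    subject_id: str
    session_index: int
    trial_index: int
    rater_id: str
    duration_s: float
    measures: tuple[BehaviorMeasure, ...]
    indices: dict[str, float | None] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        """Total number of state bouts plus point occurrences."""
        return sum(m.count for m in self.measures)

    def measure(self, behavior: str) -> BehaviorMeasure:
        for m in self.measures:
            if m.behavior == behavior:
                return m
        raise KeyError(behavior)

    def total(self, behavior: str) -> float:
        return self.measure(behavior).total_s

    def count(self, behavior: str) -> int:
        return self.measure(behavior).count

    def latency(self, behavior: str) -> float:
        return self.measure(behavior).latency_s


def summarize_trial(trial: ScoredTrial, etho: Ethogram, *, novel: str | None = None) -> MeasureSet:
    """Compute the :class:`MeasureSet` for one trial against its ethogram.

    ``novel`` overrides the ethogram's ``novel_designation`` per trial
    (counterbalanced NOR designs).
    """
    known = {b.name for b in etho.behaviors}
    extra = trial.behavior_names() - known
    if extra:
        raise SchemaMismatchError(
            f"trial scores behavior(s) absent from ethogram {etho.test_name!r}: "
            f"{', '.join(sorted(extra))}"
        )

    measures: list[BehaviorMeasure] = []
    for beh in etho.behaviors:
        if beh.kind == "state":
            mine = [b for b in trial.bouts if b.behavior == beh.name]
            total = float(sum(b.duration for b in mine))
            count = len(mine)
            first = min((b.start for b in mine), default=None)
        else:
            mine_p = [p for p in trial.points if p.behavior == beh.name]
            total = 0.0
            count = len(mine_p)
            first = min((p.t for p in mine_p), default=None)
        if first is None:
            measures.append(
                BehaviorMeasure(beh.name, 0.0, 0, trial.duration_s, True)
            )
        else:
            measures.append(BehaviorMeasure(beh.name, total, count, float(first), False))

    ms = MeasureSet(
        subject_id=trial.subject_id,
        session_index=trial.session_index,
        trial_index=trial.trial_index,
        rater_id=trial.rater_id,
        duration_s=trial.duration_s,
        measures=tuple(measures),
        indices={},
    )

    test = etho.test_name.upper()
    if test == "EPM":
        ms.indices.update(epm_measures(ms))
    elif test == "NOR":
        novel_name = novel if novel is not None else etho.novel_designation
        if novel_name is not None:
            ms.indices.update(nor_indices(ms, novel_name, etho=etho))
    return ms


def epm_measures(ms: MeasureSet, *, include_center: bool = False) -> dict[str, float | None]:
    """Elevated-plus-maze indices from an already-summarized trial.

    Requires behaviors named ``open_arm`` and ``closed_arm``; ``center`` is
    optional and excluded from the time denominator unless
    ``include_center`` is set.  An "entry" is the start of an arm bout.
    Zero denominators yield ``None`` (missing), not 0.
    """
    open_m = ms.measure("open_arm")
    closed_m = ms.measure("closed_arm")
    denom_t = open_m.total_s + closed_m.total_s
    if include_center:
        try:
            denom_t += ms.measure("center").total_s
        except KeyError:
            pass
    denom_n = open_m.count + closed_m.count

    out: dict[str, float | None] = {
        "open_entries": float(open_m.count),
        "closed_entries": float(closed_m.count),
    }
    out["pct_open_time"] = 100.0 * open_m.total_s / denom_t if denom_t > 0 else None
    out["pct_open_entries"] = 100.0 * open_m.count / denom_n if denom_n > 0 else None
    return out


def nor_indices(
    ms: MeasureSet, novel: str, *, etho: Ethogram | None = None
) -> dict[str, float | None]:
    """Novel-object-recognition discrimination and preference indices.

    ``novel`` names the object behavior designated novel; the familiar
    object is the other object behavior.  If ``etho`` is given, the
    familiar object is the other *state* behavior among
    ``{explore_A, explore_B}``-style object pairs, identified as any state
    behavior other than ``novel`` and other than a behavior named
    ``general_area``.  Without an ethogram the same rule is applied to the
    measure names.
    """
    names = [m.behavior for m in ms.measures]
    if novel not in names:
        raise SchemaMismatchError(f"novel behavior {novel!r} not present in measures")
    if etho is not None:
        candidates = [
            b.name
            for b in etho.state_behaviors
            if b.name != novel and b.name != "general_area"
        ]
    else:
        candidates = [n for n in names if n != novel and n != "general_area"]
    if len(candidates) != 1:
        raise SchemaMismatchError(
            f"cannot identify the familiar object among {candidates!r}"
        )
    familiar = candidates[0]

    t_nov = ms.total(novel)
    t_fam = ms.total(familiar)
    denom = t_nov + t_fam
    if denom <= 0:
        return {"discrimination_index": None, "preference_index": None}
    di = (t_nov - t_fam) / denom
    # derive PI from DI so the identity PI = 50 * (DI + 1) holds exactly
    pi = 50.0 * (di + 1.0)
    return {"discrimination_index": di, "preference_index": pi}


def segment_summaries(
    trial: ScoredTrial, etho: Ethogram, bin_s: float, *, novel: str | None = None
) -> list[tuple[tuple[float, float], MeasureSet]]:
    """Summarize a trial in consecutive bins of width ``bin_s``.

    Bins are ``[k*bin_s, (k+1)*bin_s)`` covering ``[0, duration)``; the
    final partial bin is included.  Returns ``((a, b), MeasureSet)`` pairs;
    per-behavior totals across bins sum to the whole-trial totals.
    """
    if not bin_s > 0:
        raise RangeError(f"bin width must be > 0, got {bin_s}")
    out = []
    n_bins = max(1, math.ceil(trial.duration_s / bin_s - 1e-12))
    for k in range(n_bins):
        a = k * bin_s
        b = min((k + 1) * bin_s, trial.duration_s)
        seg = slice_segment(trial, a, b)
        out.append(((a, b), summarize_trial(seg, etho, novel=novel)))
    return out
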