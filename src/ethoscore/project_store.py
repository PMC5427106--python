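"""Projects: protocols with ethograms, subjects, groups, and scored trials.

A project organizes one protocol: any number of behavioral tests (each an
ethogram), a roster of subjects with free-form descriptors (sex, age,
origin, ...), experimental groups (vehicle, treatment, stress, ...), and
the scored trials keyed by (subject, test, session, trial, rater).  Group
assignment may happen after scoring; re-exporting reflects the latest
assignment.

On-disk store: a single SQLite file with a documented schema (tables
``meta``, ``ethograms``, ``subjects``, ``groups``, ``trials``).  Saving is
canonical — rows are written in sorted key order with sorted-key JSON — so
save -> load -> save produces byte-identical files.  A portable JSON text
export (:meth:`Project.to_json` / :meth:`Project.from_json`) is provided
for diffing and interchange.

Results export: one RFC-4180 csv row per (subject, session, trial, rater,
segment); seconds are written with 6 decimal places; missing groups and
undefined indices are empty cells, not sentinel text.  Per-animal visual
maps are written as separate png files named
``<project>_<subject>_<test>_s<session>t<trial>_<rater>.png``.
"""

from __future__ import annotations

import csv
import json
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConflictError, ProjectError, RangeError, ReferentialError
from .ethogram import Ethogram
from .metrics import summarize_trial
from .timeline import Bout, PointOccurrence, ScoredTrial, slice_segment
from .visualmap import MapStyle, render_map, save_map

__all__ = ["Subject", "TrialKey", "Project", "export_results"]

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE ethograms (test_name TEXT PRIMARY KEY, definition TEXT NOT NULL);
CREATE TABLE groups (label TEXT PRIMARY KEY, descriptors TEXT NOT NULL);
CREATE TABLE subjects (
    subject_id TEXT PRIMARY KEY,
    group_label TEXT,
    descriptors TEXT NOT NULL
);
CREATE TABLE trials (
    subject_id TEXT NOT NULL,
    test_name TEXT NOT NULL,
    session_index INTEGER NOT NULL,
    trial_index INTEGER NOT NULL,
    rater_id TEXT NOT NULL,
    duration_s REAL NOT NULL,
    bouts TEXT NOT NULL,
    points TEXT NOT NULL,
    PRIMARY KEY (subject_id, test_name, session_index, trial_index, rater_id)
);
"""


@dataclass
class Subject:
    """One experimental animal with free-form descriptors."""

    subject_id: str
    descriptors: dict[str, str] = field(default_factory=dict)
    group: str | None = None


#: (subject_id, test_name, session_index, trial_index, rater_id)
TrialKey = tuple[str, str, int, int, str]


class Project:
    """In-memory project; persist with :meth:`save` / :meth:`load`."""

    def __init__(self, name: str):
        if not name:
            raise ProjectError("project name must be non-empty")
        self.name = name
        self.ethograms: dict[str, Ethogram] = {}
        self.subjects: dict[str, Subject] = {}
        self.groups: dict[str, dict[str, str]] = {}
        self.trials: dict[TrialKey, ScoredTrial] = {}

    # -- registration ----------------------------------------------------

    def add_ethogram(self, etho: Ethogram) -> None:
        self.ethograms[etho.test_name] = etho

    def add_subject(self, subject: Subject | str, **descriptors: str) -> Subject:
        if isinstance(subject, str):
            subject = Subject(subject, dict(descriptors))
        if subject.subject_id in self.subjects:
            raise ConflictError(f"subject {subject.subject_id!r} already registered")
        if subject.group is not None and subject.group not in self.groups:
            raise ReferentialError(f"group {subject.group!r} not registered")
        self.subjects[subject.subject_id] = subject
        return subject

    def add_group(self, label: str, **descriptors: str) -> None:
        self.groups[label] = dict(descriptors)

    def assign_group(self, subject_id: str, group_label: str) -> None:
        """Assign (or reassign) a subject to a group; latest assignment wins.

        Allowed at any time, including after scoring.
        """
        if subject_id not in self.subjects:
            raise ReferentialError(f"unknown subject {subject_id!r}")
        if group_label not in self.groups:
            raise ReferentialError(f"unknown group {group_label!r}")
        self.subjects[subject_id].group = group_label

    def record_trial(self, trial: ScoredTrial, test_name: str) -> TrialKey:
        """Persist one scored trial under (subject, test, session, trial, rater)."""
        if trial.subject_id not in self.subjects:
            raise ReferentialError(f"unknown subject {trial.subject_id!r}")
        if test_name not in self.ethograms:
            raise ReferentialError(f"unknown test {test_name!r}")
        etho = self.ethograms[test_name]
        unknown = trial.behavior_names() - {b.name for b in etho.behaviors}
        if unknown:
            raise ReferentialError(
                f"trial scores behavior(s) not in ethogram {test_name!r}: "
                f"{', '.join(sorted(unknown))}"
            )
        key: TrialKey = (
            trial.subject_id,
            test_name,
            trial.session_index,
            trial.trial_index,
            trial.rater_id,
        )
        if key in self.trials:
            raise ConflictError(f"trial already recorded for key {key}")
        self.trials[key] = trial
        return key

    def get_trial(self, key: TrialKey) -> ScoredTrial:
        return self.trials[key]

    def trials_for_test(self, test_name: str) -> dict[TrialKey, ScoredTrial]:
        return {k: t for k, t in self.trials.items() if k[1] == test_name}

    # -- JSON (portable text) --------------------------------------------

    def to_json(self) -> str:
        d = {
            "name": self.name,
            "ethograms": {n: e.to_dict() for n, e in sorted(self.ethograms.items())},
            "groups": {g: self.groups[g] for g in sorted(self.groups)},
            "subjects": {
                s.subject_id: {"descriptors": s.descriptors, "group": s.group}
                for s in (self.subjects[k] for k in sorted(self.subjects))
            },
            "trials": [
                {
                    "subject_id": k[0],
                    "test_name": k[1],
                    "session_index": k[2],
                    "trial_index": k[3],
                    "rater_id": k[4],
                    "duration_s": t.duration_s,
                    "bouts": [[b.behavior, b.start, b.end] for b in t.bouts],
                    "points": [[p.behavior, p.t] for p in t.points],
                }
                for k, t in sorted(self.trials.items())
            ],
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Project":
        d = json.loads(text)
        proj = cls(d["name"])
        for etho_d in d["ethograms"].values():
            proj.add_ethogram(Ethogram.from_dict(etho_d))
        for label, desc in d["groups"].items():
            proj.add_group(label, **desc)
        for sid, sd in d["subjects"].items():
            proj.add_subject(Subject(sid, dict(sd["descriptors"]), sd["group"]))
        for td in d["trials"]:
            trial = ScoredTrial(
                subject_id=td["subject_id"],
                duration_s=td["duration_s"],
                bouts=tuple(Bout(b, s, e) for b, s, e in td["bouts"]),
                points=tuple(PointOccurrence(b, t) for b, t in td["points"]),
                session_index=td["session_index"],
                trial_index=td["trial_index"],
                rater_id=td["rater_id"],
            )
            proj.record_trial(trial, td["test_name"])
        return proj

    # -- SQLite store ----------------------------------------------------

    def save(self, path) -> None:
        """Write the project to a SQLite file (canonical row order)."""
        path = os.fspath(path)
        if os.path.exists(path):
            os.remove(path)
        con = sqlite3.connect(path)
        try:
            con.executescript(_SCHEMA)
            con.execute("INSERT INTO meta VALUES ('name', ?)", (self.name,))
            for name in sorted(self.ethograms):
                con.execute(
                    "INSERT INTO ethograms VALUES (?, ?)",
                    (name, json.dumps(self.ethograms[name].to_dict(), sort_keys=True)),
                )
            for label in sorted(self.groups):
                con.execute(
                    "INSERT INTO groups VALUES (?, ?)",
                    (label, json.dumps(self.groups[label], sort_keys=True)),
                )
            for sid in sorted(self.subjects):
                s = self.subjects[sid]
                con.execute(
                    "INSERT INTO subjects VALUES (?, ?, ?)",
                    (sid, s.group, json.dumps(s.descriptors, sort_keys=True)),
                )
            for key in sorted(self.trials):
                t = self.trials[key]
                con.execute(
                    "INSERT INTO trials VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (
                        *key,
                        t.duration_s,
                        json.dumps([[b.behavior, b.start, b.end] for b in t.bouts]),
                        json.dumps([[p.behavior, p.t] for p in t.points]),
                    ),
                )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path) -> "Project":
        path = os.fspath(path)
        if not os.path.exists(path):
            raise ProjectError(f"no project file at {path}")
        con = sqlite3.connect(path)
        try:
            (name,) = con.execute("SELECT value FROM meta WHERE key='name'").fetchone()
            proj = cls(name)
            for _, definition in con.execute(
                "SELECT test_name, definition FROM ethograms ORDER BY test_name"
            ):
                proj.add_ethogram(Ethogram.from_dict(json.loads(definition)))
            for label, desc in con.execute(
                "SELECT label, descriptors FROM groups ORDER BY label"
            ):
                proj.add_group(label, **json.loads(desc))
            for sid, group, desc in con.execute(
                "SELECT subject_id, group_label, descriptors FROM subjects ORDER BY subject_id"
            ):
                proj.add_subject(Subject(sid, json.loads(desc), group))
            for row in con.execute(
                "SELECT subject_id, test_name, session_index, trial_index, rater_id,"
                " duration_s, bouts, points FROM trials"
                " ORDER BY subject_id, test_name, session_index, trial_index, rater_id"
            ):
                sid, test, sess, tri, rater, dur, bouts_j, points_j = row
                trial = ScoredTrial(
                    subject_id=sid,
                    duration_s=dur,
                    bouts=tuple(Bout(b, s, e) for b, s, e in json.loads(bouts_j)),
                    points=tuple(PointOccurrence(b, t) for b, t in json.loads(points_j)),
                    session_index=sess,
                    trial_index=tri,
                    rater_id=rater,
                )
                proj.record_trial(trial, test)
            return proj
        finally:
            con.close()


# ---------------------------------------------------------------------------
# csv + map export
# ---------------------------------------------------------------------------

def _fmt_s(x: float) -> str:
    return f"{x:.6f}"


def _segments(trial: ScoredTrial, bins, window):
    if bins is not None and window is not None:
        raise RangeError("specify at most one of bins and window")
    if bins is not None:
        if not bins > 0:
            raise RangeError("bin width must be > 0")
        out, a = [], 0.0
        while a < trial.duration_s - 1e-12:
            out.append((a, min(a + bins, trial.duration_s)))
            a += bins
        return out
    if window is not None:
        return [tuple(window)]
    return [(0.0, trial.duration_s)]


def export_results(
    project: Project,
    test_name: str,
    out_csv,
    *,
    bins: float | None = None,
    window: tuple[float, float] | None = None,
    maps_dir=None,
    style: MapStyle = MapStyle(),
) -> list[str]:
    """Export a results table (and optionally per-animal maps) for one test.

    Segment selection: whole trial (default), consecutive ``bins`` of a given
    width, or a single ``window`` ``(a, b)``.  Returns the list of map file
    paths written (empty when ``maps_dir`` is None).  With no recorded
    trials a header-only csv is still written.
    """
    if test_name not in project.ethograms:
        raise ReferentialError(f"unknown test {test_name!r}")
    etho = project.ethograms[test_name]
    trials = project.trials_for_test(test_name)

    desc_keys = sorted({k for s in project.subjects.values() for k in s.descriptors})
    index_names = _index_names(etho)

    header = (
        ["project", "subject_id", "group"]
        + desc_keys
        + ["test", "session", "trial", "rater", "seg_start_s", "seg_end_s"]
    )
    for b in etho.behaviors:
        header += [
            f"{b.name}_total_s",
            f"{b.name}_count",
            f"{b.name}_latency_s",
            f"{b.name}_latency_censored",
        ]
    header += ["n_events"] + index_names

    map_files: list[str] = []
    with open(out_csv, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for key in sorted(trials):
            trial = trials[key]
            subject = project.subjects[trial.subject_id]
            for a, b_end in _segments(trial, bins, window):
                seg = slice_segment(trial, a, b_end)
                ms = summarize_trial(seg, etho)
                row = [
                    project.name,
                    subject.subject_id,
                    subject.group if subject.group is not None else "",
                ]
                row += [subject.descriptors.get(k, "") for k in desc_keys]
                row += [
                    test_name,
                    trial.session_index,
                    trial.trial_index,
                    trial.rater_id,
                    _fmt_s(a),
                    _fmt_s(b_end),
                ]
                for m in ms.measures:
                    row += [
                        _fmt_s(m.total_s),
                        m.count,
                        _fmt_s(m.latency_s),
                        "true" if m.latency_censored else "false",
                    ]
                row.append(ms.n_events)
                for name in index_names:
                    v = ms.indices.get(name)
                    row.append("" if v is None else _fmt_s(v))
                writer.writerow(row)

            if maps_dir is not None:
                os.makedirs(maps_dir, exist_ok=True)
                fname = (
                    f"{project.name}_{trial.subject_id}_{test_name}"
                    f"_s{trial.session_index}t{trial.trial_index}_{trial.rater_id}.png"
                )
                fpath = os.path.join(os.fspath(maps_dir), fname)
                save_map(render_map(trial, etho, style), fpath)
                map_files.append(fpath)
    return map_files


def _index_names(etho: Ethogram) -> list[str]:
    test = etho.test_name.upper()
    if test == "EPM":
        return ["open_entries", "closed_entries", "pct_open_time", "pct_open_entries"]
    if test == "NOR":
        return ["discrimination_index", "preference_index"]
    return []
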