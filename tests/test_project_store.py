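import csv

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethoscore import (
    Bout,
    PointOccurrence,
    Project,
    ScoredTrial,
    Subject,
    builtin_template,
    export_results,
    fst_like_model,
    simulate_trial,
    subject_seed,
    summarize_trial,
)
from ethoscore.errors import ConflictError, ReferentialError


def make_project(n_subjects=2, n_raters=1, seed=0):
    fst = builtin_template("FST")
    p = Project("demo")
    p.add_ethogram(fst)
    p.add_group("vehicle")
    p.add_group("treatment")
    model = fst_like_model()
    for i in range(n_subjects):
        sid = f"R{i + 1}"
        p.add_subject(Subject(sid, {"sex": "M" if i % 2 == 0 else "F"}))
        for j in range(n_raters):
            t = simulate_trial(
                model, fst, 300.0, subject_seed(seed, i * 10 + j),
                subject_id=sid, session_index=2, rater_id=f"rater{j + 1}",
            )
            p.record_trial(t, "FST")
    return p


class TestRecordTrial:
    def test_round_trip_field_by_field(self, tmp_path):
        p = make_project()
        path = tmp_path / "p.db"
        p.save(path)
        loaded = Project.load(path)
        for key, trial in p.trials.items():
            assert loaded.get_trial(key) == trial
        assert loaded.to_json() == p.to_json()

    def test_duplicate_key_conflict(self):
        p = make_project(n_subjects=1)
        key = next(iter(p.trials))
        with pytest.raises(ConflictError):
            p.record_trial(p.trials[key], "FST")

    def test_unknown_subject(self, fst):
        p = Project("x")
        p.add_ethogram(fst)
        t = ScoredTrial("ghost", 300.0, bouts=(Bout("immobility", 0, 300),))
        with pytest.raises(ReferentialError):
            p.record_trial(t, "FST")

    def test_unknown_test(self, fst):
        p = Project("x")
        p.add_subject(Subject("R1"))
        t = ScoredTrial("R1", 300.0, bouts=(Bout("immobility", 0, 300),))
        with pytest.raises(ReferentialError):
            p.record_trial(t, "FST")

    def test_behavior_not_in_ethogram(self, fst):
        p = Project("x")
        p.add_ethogram(fst)
        p.add_subject(Subject("R1"))
        t = ScoredTrial("R1", 300.0, bouts=(Bout("flying", 0, 300),))
        with pytest.raises(ReferentialError):
            p.record_trial(t, "FST")

    def test_ten_trials_all_retrievable(self):
        p = make_project(n_subjects=5, n_raters=2)
        assert len(p.trials) == 10
        for i in range(5):
            for j in range(2):
                key = (f"R{i + 1}", "FST", 2, 1, f"rater{j + 1}")
                assert p.get_trial(key).subject_id == f"R{i + 1}"


class TestGroups:
    def test_deferred_assignment_reflected_in_export(self, tmp_path):
        p = make_project(n_subjects=1)
        out = tmp_path / "r.csv"
        export_results(p, "FST", out)
        rows = list(csv.DictReader(open(out, encoding="utf-8")))
        assert rows[0]["group"] == ""
        p.assign_group("R1", "treatment")
        export_results(p, "FST", out)
        rows = list(csv.DictReader(open(out, encoding="utf-8")))
        assert rows[0]["group"] == "treatment"

    def test_reassign_latest_wins(self):
        p = make_project(n_subjects=1)
        p.assign_group("R1", "vehicle")
        p.assign_group("R1", "treatment")
        assert p.subjects["R1"].group == "treatment"

    def test_unknown_group(self):
        p = make_project(n_subjects=1)
        with pytest.raises(ReferentialError):
            p.assign_group("R1", "stress")

    def test_unknown_subject(self):
        p = make_project(n_subjects=1)
        with pytest.raises(ReferentialError):
            p.assign_group("R99", "vehicle")


class TestExport:
    def test_whole_trial_shape(self, tmp_path):
        p = make_project(n_subjects=1)
        out = tmp_path / "r.csv"
        export_results(p, "FST", out)
        rows = list(csv.DictReader(open(out, encoding="utf-8")))
        assert len(rows) == 1
        row = rows[0]
        for beh in ("immobility", "swimming", "climbing", "head_shake"):
            for suffix in ("total_s", "count", "latency_s", "latency_censored"):
                assert f"{beh}_{suffix}" in row
        assert row["project"] == "demo"
        assert row["sex"] == "M"

    def test_bins_sum_to_whole(self, tmp_path):
        p = make_project(n_subjects=2)
        whole_csv = tmp_path / "whole.csv"
        bins_csv = tmp_path / "bins.csv"
        export_results(p, "FST", whole_csv)
        export_results(p, "FST", bins_csv, bins=60.0)
        whole = list(csv.DictReader(open(whole_csv, encoding="utf-8")))
        binned = list(csv.DictReader(open(bins_csv, encoding="utf-8")))
        assert len(binned) == 5 * len(whole)
        for wrow in whole:
            mine = [r for r in binned if r["subject_id"] == wrow["subject_id"]]
            for beh in ("immobility", "swimming", "climbing"):
                total = sum(float(r[f"{beh}_total_s"]) for r in mine)
                assert total == pytest.approx(float(wrow[f"{beh}_total_s"]), abs=1e-5)

    def test_window_export(self, tmp_path):
        p = make_project(n_subjects=1)
        out = tmp_path / "w.csv"
        export_results(p, "FST", out, window=(60.0, 120.0))
        (row,) = csv.DictReader(open(out, encoding="utf-8"))
        assert float(row["seg_start_s"]) == 60.0
        assert float(row["seg_end_s"]) == 120.0

    def test_empty_export_header_only(self, tmp_path):
        p = Project("empty")
        p.add_ethogram(builtin_template("FST"))
        out = tmp_path / "e.csv"
        export_results(p, "FST", out)
        lines = out.read_text(encoding="utf-8").strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("project,")

    def test_reimport_reproduces_measures(self, tmp_path):
        p = make_project(n_subjects=3)
        fst = p.ethograms["FST"]
        out = tmp_path / "r.csv"
        export_results(p, "FST", out)
        rows = {r["subject_id"]: r for r in csv.DictReader(open(out, encoding="utf-8"))}
        for key, trial in p.trials.items():
            ms = summarize_trial(trial, fst)
            row = rows[trial.subject_id]
            for m in ms.measures:
                assert float(row[f"{m.behavior}_total_s"]) == pytest.approx(m.total_s, abs=1e-6)
                assert int(row[f"{m.behavior}_count"]) == m.count
                assert float(row[f"{m.behavior}_latency_s"]) == pytest.approx(
                    m.latency_s, abs=1e-6
                )
            assert int(row["n_events"]) == ms.n_events

    def test_nor_index_columns_and_missing_blank(self, tmp_path):
        nor = builtin_template("NOR")
        p = Project("np")
        p.add_ethogram(nor)
        p.add_subject(Subject("R1"))
        p.add_subject(Subject("R2"))
        p.record_trial(
            ScoredTrial(
                "R1", 300.0,
                bouts=(Bout("explore_A", 0, 10), Bout("explore_B", 10, 40)),
            ),
            "NOR",
        )
        # R2 never explored either object: indices undefined -> blank cells
        p.record_trial(
            ScoredTrial("R2", 300.0, bouts=(Bout("general_area", 0, 300),)), "NOR"
        )
        out = tmp_path / "nor.csv"
        export_results(p, "NOR", out)
        rows = {r["subject_id"]: r for r in csv.DictReader(open(out, encoding="utf-8"))}
        assert float(rows["R1"]["discrimination_index"]) == pytest.approx(0.5)
        assert float(rows["R1"]["preference_index"]) == pytest.approx(75.0)
        assert rows["R2"]["discrimination_index"] == ""
        assert rows["R2"]["preference_index"] == ""

    def test_map_files_written_with_naming_scheme(self, tmp_path):
        p = make_project(n_subjects=2)
        out = tmp_path / "r.csv"
        files = export_results(p, "FST", out, maps_dir=tmp_path / "maps")
        assert len(files) == 2
        names = sorted(f.split("/")[-1] for f in files)
        assert names[0] == "demo_R1_FST_s2t1_rater1.png"
        for f in files:
            assert (tmp_path / "maps" / f.split("/")[-1]).exists()


class TestPersistence:
    def test_save_load_save_byte_identical(self, tmp_path):
        p = make_project(n_subjects=3, n_raters=2)
        p.assign_group("R1", "vehicle")
        a, b = tmp_path / "a.db", tmp_path / "b.db"
        p.save(a)
        Project.load(a).save(b)
        assert a.read_bytes() == b.read_bytes()

    def test_json_round_trip(self):
        p = make_project(n_subjects=2)
        p.assign_group("R2", "treatment")
        q = Project.from_json(p.to_json())
        assert q.to_json() == p.to_json()

    def test_load_missing_file(self, tmp_path):
        with pytest.raises(Exception):
            Project.load(tmp_path / "nope.db")


@settings(max_examples=20, deadline=None)
@given(ops=st.lists(st.integers(0, 2), min_size=1, max_size=15), seed=st.integers(0, 1000))
def test_referential_integrity_random_op_sequences(ops, seed):
    """After any sequence of valid operations every trial still references a
    registered subject and ethogram, and keys stay unique."""
    rng = np.random.default_rng(seed)
    fst = builtin_template("FST")
    p = Project("rand")
    p.add_ethogram(fst)
    p.add_group("g1")
    n_sub = 0
    for op in ops:
        if op == 0:
            n_sub += 1
            p.add_subject(Subject(f"S{n_sub}"))
        elif op == 1 and n_sub:
            sid = f"S{int(rng.integers(n_sub)) + 1}"
            trial_idx = len([k for k in p.trials if k[0] == sid]) + 1
            t = ScoredTrial(
                sid, 60.0, bouts=(Bout("immobility", 0, 60),), trial_index=trial_idx
            )
            p.record_trial(t, "FST")
        elif op == 2 and n_sub:
            p.assign_group(f"S{int(rng.integers(n_sub)) + 1}", "g1")
    keys = list(p.trials)
    assert len(set(keys)) == len(keys)
    for k in keys:
        assert k[0] in p.subjects and k[1] in p.ethograms
    for s in p.subjects.values():
        assert s.group is None or s.group in p.groups
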