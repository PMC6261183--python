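"""Transaction-managed revisions: locking, atomicity, diffs, rollback."""

import random
import threading

import pytest

from dicom_curator import (
    RevisionNotFound,
    SubjectLocked,
    UnresolvedTarget,
)
from dicom_curator import fixtures as fx
from dicom_curator import revisions as rev


def _import(ws, paths, subject="P1"):
    ws.import_files(paths, "C", subject)
    ws.assign_nicknames(subject)


def _spec(subject, targets, ops, origin="test"):
    return rev.EditSpecification(
        subject=subject,
        targets=targets,
        operations=[rev.EditOperation(*op) for op in ops],
        origin=origin,
        user="tester",
    )


def _head_digests(ws, subject):
    return sorted(r["file_digest"] for r in ws.head_file_rows(subject))


def _head_bytes(ws, subject):
    return {
        r["sop_uid"]: ws.read_object(r["file_digest"])
        for r in ws.head_file_rows(subject)
    }


class TestLocking:
    def test_second_begin_raises(self, workspace, clean_series):
        _import(workspace, clean_series(n=2))
        h = rev.begin_edit(workspace, "P1")
        with pytest.raises(SubjectLocked):
            rev.begin_edit(workspace, "P1")
        rev.abort_edit(h)

    def test_different_subjects_do_not_contend(self, workspace, clean_series):
        _import(workspace, clean_series(n=1, subject="A"), "A")
        _import(workspace, clean_series(n=1, subject="B"), "B")
        ha = rev.begin_edit(workspace, "A")
        hb = rev.begin_edit(workspace, "B")
        rev.abort_edit(ha)
        rev.abort_edit(hb)

    def test_abort_releases(self, workspace, clean_series):
        _import(workspace, clean_series(n=1))
        rev.abort_edit(rev.begin_edit(workspace, "P1"))
        rev.abort_edit(rev.begin_edit(workspace, "P1"))

    def test_stale_lock_expires(self, workspace, clean_series):
        _import(workspace, clean_series(n=1))
        rev.begin_edit(workspace, "P1", timeout=0.0)  # instantly stale
        rev.abort_edit(rev.begin_edit(workspace, "P1"))

    def test_single_writer_under_contention(self, workspace, clean_series):
        _import(workspace, clean_series(n=1))
        outcomes = []
        barrier = threading.Barrier(8)

        def attempt():
            barrier.wait()
            try:
                h = rev.begin_edit(workspace, "P1")
                outcomes.append(h)
            except SubjectLocked:
                outcomes.append(None)

        threads = [threading.Thread(target=attempt) for _ in range(8)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        winners = [h for h in outcomes if h is not None]
        assert len(winners) == 1
        rev.abort_edit(winners[0])


class TestApplyEdit:
    def test_copy_on_write_shares_untargeted_files(self, workspace, clean_series):
        _import(workspace, clean_series(n=6))
        before = _head_digests(workspace, "P1")
        nicks = sorted(r["nickname"] for r in workspace.head_file_rows("P1"))
        spec = _spec("P1", nicks[1:], [("0020,0052", "set", "1.2.3")])
        r = rev.apply_spec(workspace, spec)
        after = _head_digests(workspace, "P1")
        assert len(after) == 6
        assert len(set(after) & set(before)) == 1  # only the untargeted file
        assert r.parent is not None and r.origin == "test" and r.user == "tester"

    def test_empty_effect_edit_creates_revision_with_empty_diff(
        self, workspace, clean_series
    ):
        _import(workspace, clean_series(n=2))
        head0 = workspace.head("P1")
        rows = workspace.head_file_rows("P1")
        # set the Series Description to the value it already has
        spec = _spec(
            "P1", [rows[0]["nickname"]], [("0008,103E", "set", "SYNTHETIC")]
        )
        r = rev.apply_spec(workspace, spec)
        assert r.parent == head0
        assert rev.diff(workspace, "P1", head0, r.revision_id).empty

    def test_unknown_nickname_is_atomic(self, workspace, clean_series):
        _import(workspace, clean_series(n=3))
        head0 = workspace.head("P1")
        census = _head_digests(workspace, "P1")
        spec = _spec("P1", ["F999999"], [("0020,0052", "set", "1.2.3")])
        with pytest.raises(UnresolvedTarget):
            rev.apply_spec(workspace, spec)
        assert workspace.head("P1") == head0
        assert _head_digests(workspace, "P1") == census

    def test_bad_path_is_atomic(self, workspace, clean_series):
        _import(workspace, clean_series(n=3))
        head0 = workspace.head("P1")
        rows = workspace.head_file_rows("P1")
        spec = _spec("P1", [rows[0]["nickname"]], [("nonsense", "set", "x")])
        with pytest.raises(Exception):
            rev.apply_spec(workspace, spec)
        assert workspace.head("P1") == head0
        # lock was released despite the failure
        rev.abort_edit(rev.begin_edit(workspace, "P1"))

    def test_entity_query_targets(self, workspace, clean_series):
        _import(workspace, clean_series(n=4))
        series_uid = workspace.head_file_rows("P1")[0]["series_uid"]
        spec = _spec(
            "P1",
            {"level": "series", "entity_id": series_uid},
            [("0008,103E", "set", "RENAMED")],
        )
        rev.apply_spec(workspace, spec)
        vals = {
            v
            for _, v, _ in workspace.query_entity_attribute_values(
                "series", "0008,103E", subject="P1"
            )
        }
        assert vals == {"RENAMED"}

    def test_spec_json_roundtrip(self):
        spec = _spec("P1", ["F000001"], [("0020,0052", "set", "1.2.3")])
        again = rev.EditSpecification.from_json(spec.to_json())
        assert again == spec


class TestDiff:
    def test_diff_of_revision_with_itself_is_empty(self, workspace, clean_series):
        _import(workspace, clean_series(n=2))
        head = workspace.head("P1")
        assert rev.diff(workspace, "P1", head, head).empty

    def test_frame_of_reference_edit_diff(self, workspace, clean_series):
        _import(workspace, clean_series(n=6))
        head0 = workspace.head("P1")
        nicks = sorted(r["nickname"] for r in workspace.head_file_rows("P1"))
        spec = _spec("P1", nicks[1:], [("0020,0052", "set", "9.9.9")])
        r = rev.apply_spec(workspace, spec)
        d = rev.diff(workspace, "P1", head0, r.revision_id)
        changed = [(f.key, f.changed) for f in d.files if not f.empty]
        assert len(changed) == 5
        for _, deltas in changed:
            assert [p for p, _, _ in deltas] == ["0020,0052"]
            assert all(new == "9.9.9" for _, _, new in deltas)

    def test_diff_is_symmetric_up_to_swap(self, workspace, clean_series):
        _import(workspace, clean_series(n=3))
        head0 = workspace.head("P1")
        rows = workspace.head_file_rows("P1")
        spec = _spec("P1", [rows[0]["nickname"]], [("0010,1030", "set", "70")])
        r = rev.apply_spec(workspace, spec)
        fwd = rev.diff(workspace, "P1", head0, r.revision_id)
        back = rev.diff(workspace, "P1", r.revision_id, head0)
        fwd_changed = {
            (f.key, p, old, new) for f in fwd.files for p, old, new in f.changed
        }
        back_changed = {
            (f.key, p, new, old) for f in back.files for p, old, new in f.changed
        }
        fwd_added = {(f.key, p, v) for f in fwd.files for p, v in f.added}
        back_removed = {(f.key, p, v) for f in back.files for p, v in f.removed}
        assert fwd_changed == back_changed and fwd_added == back_removed


class TestRollback:
    def test_rollback_restores_bytes_exactly(self, workspace, clean_series):
        _import(workspace, clean_series(n=4))
        head0 = workspace.head("P1")
        before = _head_bytes(workspace, "P1")
        nicks = [r["nickname"] for r in workspace.head_file_rows("P1")]
        rev.apply_spec(
            workspace, _spec("P1", nicks, [("0020,0052", "set", "7.7.7")])
        )
        assert _head_bytes(workspace, "P1") != before
        rev.rollback(workspace, "P1", head0)
        assert _head_bytes(workspace, "P1") == before
        assert rev.diff(workspace, "P1", head0, workspace.head("P1")).empty

    def test_rollback_to_head_is_noop(self, workspace, clean_series):
        _import(workspace, clean_series(n=2))
        head0 = workspace.head("P1")
        rev.rollback(workspace, "P1", head0)
        assert workspace.head("P1") == head0

    def test_unknown_revision(self, workspace, clean_series):
        _import(workspace, clean_series(n=1))
        with pytest.raises(RevisionNotFound):
            rev.rollback(workspace, "P1", 999)

    def test_branching_history_retained(self, workspace, clean_series):
        _import(workspace, clean_series(n=2))
        root = workspace.head("P1")
        nicks = [r["nickname"] for r in workspace.head_file_rows("P1")]
        r1 = rev.apply_spec(
            workspace, _spec("P1", nicks, [("0008,103E", "set", "BRANCH-A")])
        )
        rev.rollback(workspace, "P1", root)
        r2 = rev.apply_spec(
            workspace, _spec("P1", nicks, [("0008,103E", "set", "BRANCH-B")])
        )
        log = rev.revision_log(workspace, "P1")
        parents = {r.revision_id: r.parent for r in log}
        assert parents[r1.revision_id] == root and parents[r2.revision_id] == root
        assert {r1.revision_id, r2.revision_id} <= set(parents)
        # audit completeness: every revision carries creation metadata
        assert all(r.created and r.user and r.origin for r in log)


EDITABLE_TAGS = ["0008,103E", "0010,1030", "0020,0052", "0018,0015", "0008,0050"]


def test_randomized_edit_sequence_rollback_identity(workspace, clean_series):
    """20 random edits; every recorded state is reachable again by rollback
    with byte-identical files, and failed edits never move head."""
    _import(workspace, clean_series(n=5))
    rng = random.Random(20180102)
    states = {workspace.head("P1"): _head_bytes(workspace, "P1")}
    for step in range(20):
        nicks = [r["nickname"] for r in workspace.head_file_rows("P1")]
        kind = rng.random()
        if kind < 0.15:  # a doomed edit: unknown target
            with pytest.raises(UnresolvedTarget):
                rev.apply_spec(
                    workspace,
                    _spec("P1", ["F424242"], [("0008,103E", "set", "X")]),
                )
            continue
        tag = rng.choice(EDITABLE_TAGS)
        targets = rng.sample(nicks, rng.randint(1, len(nicks)))
        if kind < 0.3:
            ops = [(tag, "delete", None)]
        else:
            # digit strings are legal for every VR in the pool (LO/DS/UI/CS/SH)
            ops = [(tag, "set", f"{step}{rng.randint(0, 9)}")]
        r = rev.apply_spec(workspace, _spec("P1", targets, ops, origin=f"s{step}"))
        states[r.revision_id] = _head_bytes(workspace, "P1")
    for revision_id in rng.sample(sorted(states), 6):
        rev.rollback(workspace, "P1", revision_id)
        assert _head_bytes(workspace, "P1") == states[revision_id]
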