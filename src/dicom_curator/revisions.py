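"""Transaction-managed, revision-tracked editing with rollback.

Edits are applied copy-on-write against a content-addressed object store:
a revision is an immutable snapshot of a subject's file set (a list of
file-digest references) plus audit metadata — creation time, user, origin
(the operation or script that requested the edit) and a parent pointer.
Untargeted files are shared by reference between parent and child;
targeted files are rewritten into new objects.

Exclusive access for the duration of an edit is enforced with a per-subject
lock (a database row with an expiry timestamp; stale locks self-expire).
Rollback moves the subject's head pointer to an earlier revision — nothing
is ever deleted, so the audit trail is permanent and editing after a
rollback simply branches the revision graph.
"""

from __future__ import annotations

import json
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import model
from .db import Workspace, _now
from .errors import (
    BadPath,
    RevisionNotFound,
    SequenceIndexOutOfRange,
    SubjectLocked,
    UnresolvedTarget,
)
from .model import ElementPath

SPEC_SCHEMA_VERSION = 1

LOCK_TIMEOUT_SECONDS = 3600.0  # stale locks expire after an hour


@dataclass
class EditOperation:
    path: str  # rendered ElementPath
    action: str  # "set" | "delete"
    value: Optional[str] = None
    vr: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"path": self.path, "action": self.action}
        if self.value is not None:
            d["value"] = self.value
        if self.vr is not None:
            d["vr"] = self.vr
        return d


@dataclass
class EditSpecification:
    """Declarative description of one edit.

    ``targets`` is either a list of file nicknames or a query dict
    ``{"level": "series", "entity_id": "<uid>"}``; it must resolve to at
    least one file under the subject's head revision.
    """

    subject: str
    targets: Union[list[str], dict]
    operations: list[EditOperation]
    origin: str = "api"
    user: str = "curator"

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SPEC_SCHEMA_VERSION,
                "subject": self.subject,
                "targets": self.targets,
                "operations": [op.to_dict() for op in self.operations],
                "origin": self.origin,
                "user": self.user,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EditSpecification":
        data = json.loads(text)
        return cls(
            subject=data["subject"],
            targets=data["targets"],
            operations=[
                EditOperation(
                    path=op["path"],
                    action=op["action"],
                    value=op.get("value"),
                    vr=op.get("vr"),
                )
                for op in data["operations"]
            ],
            origin=data.get("origin", "spec"),
            user=data.get("user", "curator"),
        )


@dataclass
class Revision:
    revision_id: int
    subject: str
    parent: Optional[int]
    created: str
    user: str
    origin: str

    @classmethod
    def from_row(cls, row) -> "Revision":
        return cls(
            revision_id=row["revision_id"],
            subject=row["subject"],
            parent=row["parent"],
            created=row["created"],
            user=row["user"],
            origin=row["origin"],
        )


@dataclass
class FileDiff:
    key: str  # SOP Instance UID or nickname
    added: list[tuple[str, str]] = field(default_factory=list)  # (path, new)
    removed: list[tuple[str, str]] = field(default_factory=list)  # (path, old)
    changed: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.added or self.removed or self.changed)

    def to_dict(self) -> dict:
        return {
            "file": self.key,
            "added": [{"path": p, "new": v} for p, v in self.added],
            "removed": [{"path": p, "old": v} for p, v in self.removed],
            "changed": [
                {"path": p, "old": o, "new": n} for p, o, n in self.changed
            ],
        }


@dataclass
class RevisionDiff:
    revision_a: int
    revision_b: int
    files: list[FileDiff]
    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return (
            not self.only_in_a
            and not self.only_in_b
            and all(f.empty for f in self.files)
        )

    def to_dict(self) -> dict:
        return {
            "revision_a": self.revision_a,
            "revision_b": self.revision_b,
            "only_in_a": self.only_in_a,
            "only_in_b": self.only_in_b,
            "files": [f.to_dict() for f in self.files if not f.empty],
        }


class EditHandle:
    """Exclusive permission to apply exactly one edit to a subject."""

    def __init__(self, ws: Workspace, subject: str, token: str) -> None:
        self.ws = ws
        self.subject = subject
        self.token = token
        self.live = True


def begin_edit(
    ws: Workspace, subject: str, timeout: float = LOCK_TIMEOUT_SECONDS
) -> EditHandle:
    """Acquire the subject lock; raises :class:`SubjectLocked` when another
    live handle holds it (retry later).  Expired locks are reclaimed."""
    token = uuid.uuid4().hex
    now = time.time()
    conn = ws.new_connection()
    try:
        conn.execute("BEGIN IMMEDIATE")
        conn.execute("DELETE FROM locks WHERE subject=? AND expires<=?", (subject, now))
        try:
            conn.execute(
                "INSERT INTO locks (subject, token, expires) VALUES (?,?,?)",
                (subject, token, now + timeout),
            )
        except Exception:
            conn.rollback()
            raise SubjectLocked(subject)
        conn.commit()
    finally:
        conn.close()
    return EditHandle(ws, subject, token)


def abort_edit(handle: EditHandle) -> None:
    _release(handle)


def _release(handle: EditHandle) -> None:
    handle.ws.conn.execute(
        "DELETE FROM locks WHERE subject=? AND token=?",
        (handle.subject, handle.token),
    )
    handle.ws.conn.commit()
    handle.live = False


def _check_handle(handle: EditHandle) -> None:
    if not handle.live:
        raise SubjectLocked(f"{handle.subject}: handle already used or aborted")
    row = handle.ws.conn.execute(
        "SELECT token, expires FROM locks WHERE subject=?", (handle.subject,)
    ).fetchone()
    if row is None or row["token"] != handle.token or row["expires"] <= time.time():
        raise SubjectLocked(f"{handle.subject}: lock lost or expired")


def resolve_targets(ws: Workspace, spec: EditSpecification) -> list:
    """Head file rows addressed by the spec; raises
    :class:`UnresolvedTarget` on unknown nicknames or an empty result."""
    try:
        head_rows = ws.head_file_rows(spec.subject)
    except Exception:
        raise UnresolvedTarget(f"subject {spec.subject!r} has no head revision")
    if isinstance(spec.targets, dict):
        key = {"patient": "patient_id", "study": "study_uid", "series": "series_uid"}[
            spec.targets["level"]
        ]
        rows = [r for r in head_rows if r[key] == spec.targets["entity_id"]]
        if not rows:
            raise UnresolvedTarget(f"no files match query {spec.targets}")
        return rows
    by_nick = {r["nickname"]: r for r in head_rows}
    rows = []
    for nick in spec.targets:
        if nick not in by_nick:
            raise UnresolvedTarget(f"{spec.subject}: unknown file nickname {nick!r}")
        rows.append(by_nick[nick])
    if not rows:
        raise UnresolvedTarget("empty target list")
    return rows


def apply_edit(handle: EditHandle, spec: EditSpecification) -> Revision:
    """Apply one edit specification, producing a new head revision.

    Atomic: any failure (unresolved target, bad path, out-of-range
    sequence index) leaves the head, the database and the store untouched.
    The lock is released whether the edit succeeds or fails.
    """
    ws = handle.ws
    try:
        _check_handle(handle)
        if not spec.operations:
            raise BadPath("edit specification has no operations")
        if spec.subject != handle.subject:
            raise UnresolvedTarget(
                f"handle is for {handle.subject!r}, spec for {spec.subject!r}"
            )
        paths = [ElementPath.parse(op.path) for op in spec.operations]
        targets = resolve_targets(ws, spec)

        # rewrite every target in memory first; nothing is recorded yet
        rewritten: list[tuple[object, bytes, str]] = []  # (old row, bytes, digest)
        for row in targets:
            pds = model.parse_bytes(ws.read_object(row["file_digest"]))
            for op, epath in zip(spec.operations, paths):
                pds = model.mutate_element(
                    pds, epath, op.action, value=op.value, vr=op.vr
                )
            data = pds.serialize()
            rewritten.append((row, data, model.compute_file_digest(data)))

        cur = ws.conn.cursor()
        replaced: dict[int, int] = {}
        for row, data, digest in rewritten:
            if digest == row["file_digest"]:
                continue  # no-effect rewrite shares the parent's object
            existing = cur.execute(
                "SELECT file_id FROM files WHERE subject=? AND file_digest=?",
                (spec.subject, digest),
            ).fetchone()
            if existing is not None:
                # the rewrite reproduced bytes already in the store (e.g. an
                # edit that reverts an earlier one) — share that record
                replaced[row["file_id"]] = existing["file_id"]
                continue
            ws.object_path(digest).write_bytes(data)
            pds = model.parse_bytes(data)
            new_id = ws._insert_file_record(
                cur,
                pds,
                data,
                digest,
                row["collection"],
                row["subject"],
                nickname=row["nickname"],
            )
            replaced[row["file_id"]] = new_id
        rev_id = ws._advance_head(
            cur,
            spec.subject,
            [],
            origin=spec.origin,
            replaced=replaced,
            user=spec.user,
        )
        ws.log("edit", f"{spec.subject}: rev {rev_id} ({spec.origin})")
        ws.conn.commit()
        return Revision.from_row(ws.revision(rev_id))
    except Exception:
        ws.conn.rollback()
        raise
    finally:
        _release(handle)


def apply_spec(ws: Workspace, spec: EditSpecification) -> Revision:
    """Convenience begin + apply for scripted edits."""
    handle = begin_edit(ws, spec.subject)
    return apply_edit(handle, spec)


# ---------------------------------------------------------------------------
# diff


def _element_map(ws: Workspace, file_digest: str) -> dict[str, tuple[str, str]]:
    pds = model.parse_bytes(ws.read_object(file_digest))
    out = {}
    for row in model.iter_element_rows(pds):
        out[row.path] = (row.vr, row.value_text)
    # pixel payload identity participates via its digest
    digest = model.compute_pixel_digest(pds)
    if not digest.is_no_pixels:
        out["7FE0,0010"] = ("OW", f"<pixel digest {digest.hex}>")
    return out


def diff(ws: Workspace, subject: str, rev_a: int, rev_b: int) -> RevisionDiff:
    """Element-level differences between two revisions of one subject.

    Files pair by SOP Instance UID, falling back to nickname; files present
    on only one side are listed separately.
    """
    rows_a = {_pair_key(r): r for r in ws.revision_file_rows(rev_a)}
    rows_b = {_pair_key(r): r for r in ws.revision_file_rows(rev_b)}
    for rev in (rev_a, rev_b):
        if ws.revision(rev)["subject"] != subject:
            raise RevisionNotFound(f"revision {rev} does not belong to {subject}")
    diffs = []
    for key in sorted(set(rows_a) & set(rows_b)):
        ra, rb = rows_a[key], rows_b[key]
        fd = FileDiff(key=key)
        if ra["file_digest"] != rb["file_digest"]:
            ea = _element_map(ws, ra["file_digest"])
            eb = _element_map(ws, rb["file_digest"])
            for path in sorted(set(ea) | set(eb)):
                if path not in eb:
                    fd.removed.append((path, ea[path][1]))
                elif path not in ea:
                    fd.added.append((path, eb[path][1]))
                elif ea[path] != eb[path]:
                    fd.changed.append((path, ea[path][1], eb[path][1]))
        diffs.append(fd)
    return RevisionDiff(
        revision_a=rev_a,
        revision_b=rev_b,
        files=diffs,
        only_in_a=sorted(set(rows_a) - set(rows_b)),
        only_in_b=sorted(set(rows_b) - set(rows_a)),
    )


def _pair_key(row) -> str:
    return row["sop_uid"] or row["nickname"]


# ---------------------------------------------------------------------------
# rollback / history


def rollback(ws: Workspace, subject: str, target_revision: int) -> Revision:
    """Move the subject's head to an earlier (or any recorded) revision.

    No revision is deleted; editing afterwards branches the graph, and the
    audit log records the pointer move."""
    row = ws.revision(target_revision)
    if row["subject"] != subject:
        raise RevisionNotFound(
            f"revision {target_revision} does not belong to {subject}"
        )
    ws.conn.execute(
        "INSERT INTO heads (subject, revision_id) VALUES (?,?)"
        " ON CONFLICT(subject) DO UPDATE SET revision_id=excluded.revision_id",
        (subject, target_revision),
    )
    ws.log("rollback", f"{subject}: head -> rev {target_revision}")
    ws.conn.commit()
    return Revision.from_row(row)


def revision_log(ws: Workspace, subject: str) -> list[Revision]:
    rows = ws.conn.execute(
        "SELECT * FROM revisions WHERE subject=? ORDER BY revision_id", (subject,)
    ).fetchall()
    return [Revision.from_row(r) for r in rows]
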