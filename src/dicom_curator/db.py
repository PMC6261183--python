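"""The intake workspace: a permissive "DICOM as it is" database.

A workspace is a directory holding one embedded SQLite database, a
content-addressed object store (files keyed by whole-file MD5) and a
reports directory.  The schema deliberately enforces *no* DICOM hierarchy:
entity keys are plain nullable columns, so a series whose files point at
two different studies, or a series with six different Frame of Reference
UIDs, imports without complaint — such defects are found by queries, not
rejected at the door.

Every parseable file contributes a file record (digests, entity keys,
positional attributes) plus one element row per element occurrence, nested
sequence elements included.  Pixel value bytes are not copied into the
element table; the pixel digest plus the stored object stand in for them.

Nicknames are short, persistent, subject-scoped aliases assigned in
deterministic counter order: files ``F000001``…, series ``SE0001``…,
studies ``ST01``….  A nickname is never reassigned; two subjects may reuse
the same nickname string.
"""

from __future__ import annotations

import datetime as _dt
import sqlite3
import uuid
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import model
from .errors import RevisionNotFound, UnknownSubject
from .model import NO_PIXELS, ParsedDataset, Tag

_SCHEMA = """
CREATE TABLE IF NOT EXISTS subjects (
    subject TEXT PRIMARY KEY,
    collection TEXT NOT NULL,
    site TEXT
);
CREATE TABLE IF NOT EXISTS files (
    file_id INTEGER PRIMARY KEY,
    collection TEXT NOT NULL,
    subject TEXT NOT NULL,
    import_time TEXT NOT NULL,
    storage_path TEXT NOT NULL,
    file_digest TEXT NOT NULL,
    pixel_digest TEXT NOT NULL,
    patient_id TEXT,
    study_uid TEXT,
    series_uid TEXT,
    sop_uid TEXT,
    sop_class TEXT,
    frame_of_reference_uid TEXT,
    instance_number INTEGER,
    z_offset REAL,
    nickname TEXT NOT NULL,
    parse_notes TEXT,
    UNIQUE (subject, file_digest)
);
CREATE INDEX IF NOT EXISTS idx_files_series ON files (series_uid);
CREATE INDEX IF NOT EXISTS idx_files_pixel ON files (pixel_digest);
CREATE TABLE IF NOT EXISTS elements (
    file_id INTEGER NOT NULL REFERENCES files (file_id),
    ord INTEGER NOT NULL,
    path TEXT NOT NULL,
    vr TEXT NOT NULL,
    value BLOB,
    value_text TEXT
);
CREATE INDEX IF NOT EXISTS idx_elements_file ON elements (file_id);
CREATE INDEX IF NOT EXISTS idx_elements_path ON elements (path);
CREATE TABLE IF NOT EXISTS nicknames (
    scope_subject TEXT NOT NULL,
    kind TEXT NOT NULL CHECK (kind IN ('file', 'series', 'study')),
    nickname TEXT NOT NULL,
    target TEXT NOT NULL,
    UNIQUE (scope_subject, kind, nickname),
    UNIQUE (scope_subject, kind, target)
);
CREATE TABLE IF NOT EXISTS revisions (
    revision_id INTEGER PRIMARY KEY,
    subject TEXT NOT NULL,
    parent INTEGER REFERENCES revisions (revision_id),
    created TEXT NOT NULL,
    user TEXT NOT NULL,
    origin TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS revision_files (
    revision_id INTEGER NOT NULL REFERENCES revisions (revision_id),
    file_id INTEGER NOT NULL REFERENCES files (file_id)
);
CREATE INDEX IF NOT EXISTS idx_revfiles ON revision_files (revision_id);
CREATE TABLE IF NOT EXISTS heads (
    subject TEXT PRIMARY KEY,
    revision_id INTEGER NOT NULL REFERENCES revisions (revision_id)
);
CREATE TABLE IF NOT EXISTS locks (
    subject TEXT PRIMARY KEY,
    token TEXT NOT NULL,
    expires REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS digest_blocklist (
    pixel_digest TEXT PRIMARY KEY,
    note TEXT
);
CREATE TABLE IF NOT EXISTS audit_log (
    ts TEXT NOT NULL,
    user TEXT NOT NULL,
    action TEXT NOT NULL,
    detail TEXT
);
"""


class ImportReport:
    """Outcome of one import batch."""

    def __init__(self) -> None:
        self.imported: int = 0
        self.skipped_duplicates: int = 0
        self.unparseable: list[tuple[str, str]] = []  # (path, reason)

    def __repr__(self) -> str:
        return (
            f"ImportReport(imported={self.imported}, "
            f"skipped_duplicates={self.skipped_duplicates}, "
            f"unparseable={len(self.unparseable)})"
        )


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


class Workspace:
    """One curation workspace rooted at a directory."""

    def __init__(
        self, root: Union[str, Path], user: str = "curator", create: bool = True
    ) -> None:
        self.root = Path(root)
        self.user = user
        if create:
            (self.root / "objects").mkdir(parents=True, exist_ok=True)
            (self.root / "reports").mkdir(parents=True, exist_ok=True)
        self.db_path = self.root / "db.sqlite"
        self._conn = sqlite3.connect(self.db_path, check_same_thread=False)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- plumbing ---------------------------------------------------------

    @property
    def conn(self) -> sqlite3.Connection:
        return self._conn

    def new_connection(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.db_path, timeout=10)
        conn.row_factory = sqlite3.Row
        return conn

    def close(self) -> None:
        self._conn.close()

    def object_path(self, file_digest: str) -> Path:
        return self.root / "objects" / file_digest

    def store_object(self, data: bytes) -> str:
        digest = model.compute_file_digest(data)
        path = self.object_path(digest)
        if not path.exists():
            path.write_bytes(data)
        return digest

    def read_object(self, file_digest: str) -> bytes:
        return self.object_path(file_digest).read_bytes()

    def log(self, action: str, detail: str = "") -> None:
        self._conn.execute(
            "INSERT INTO audit_log (ts, user, action, detail) VALUES (?,?,?,?)",
            (_now(), self.user, action, detail),
        )

    # -- import -----------------------------------------------------------

    def import_files(
        self,
        paths: Iterable[Union[str, Path]],
        collection: str,
        subject: str,
        site: Optional[str] = None,
    ) -> ImportReport:
        """Import every parseable file; unparseable files are listed, never
        silently dropped.  Re-importing identical bytes is a no-op (matched
        by whole-file digest).  New files extend the subject's head revision
        via a fresh child revision (or create the root revision)."""
        if not collection or not subject:
            raise ValueError("collection and subject must be nonempty")
        report = ImportReport()
        cur = self._conn.cursor()
        cur.execute(
            "INSERT OR IGNORE INTO subjects (subject, collection, site) VALUES (?,?,?)",
            (subject, collection, site),
        )
        new_ids: list[int] = []
        for path in paths:
            path = Path(path)
            data = path.read_bytes()
            file_digest = model.compute_file_digest(data)
            row = cur.execute(
                "SELECT file_id FROM files WHERE subject=? AND file_digest=?",
                (subject, file_digest),
            ).fetchone()
            if row is not None:
                report.skipped_duplicates += 1
                continue
            try:
                pds = model.parse_bytes(data, origin=str(path))
            except model.UnparseableStream as exc:
                report.unparseable.append((str(path), str(exc)))
                continue
            self.object_path(file_digest).write_bytes(data)
            fid = self._insert_file_record(
                cur, pds, data, file_digest, collection, subject
            )
            new_ids.append(fid)
            report.imported += 1
        if new_ids:
            self._advance_head(cur, subject, new_ids, origin="import")
        self.log("import", f"{subject}: {report!r}")
        self._conn.commit()
        return report

    def _insert_file_record(
        self,
        cur: sqlite3.Cursor,
        pds: ParsedDataset,
        data: bytes,
        file_digest: str,
        collection: str,
        subject: str,
        nickname: Optional[str] = None,
    ) -> int:
        keys = model.extract_entity_keys(pds)
        pixel = model.compute_pixel_digest(pds)
        z = _z_offset(pds)
        instance = _int_or_none(model.top_level_text(pds.dataset, Tag(0x0020, 0x0013)))
        if nickname is None:
            nickname = self._next_nickname(cur, subject, "file")
        cur.execute(
            "INSERT INTO files (collection, subject, import_time, storage_path,"
            " file_digest, pixel_digest, patient_id, study_uid, series_uid,"
            " sop_uid, sop_class, frame_of_reference_uid, instance_number,"
            " z_offset, nickname, parse_notes)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                collection,
                subject,
                _now(),
                str(self.object_path(file_digest)),
                file_digest,
                pixel.hex,
                keys.patient_id,
                keys.study_uid,
                keys.series_uid,
                keys.sop_uid,
                keys.sop_class,
                keys.frame_of_reference_uid,
                instance,
                z,
                nickname,
                "\n".join(pds.parse_notes) or None,
            ),
        )
        fid = cur.lastrowid
        cur.execute(
            "INSERT OR IGNORE INTO nicknames (scope_subject, kind, nickname, target)"
            " VALUES (?,?,?,?)",
            (subject, "file", nickname, str(fid)),
        )
        rows = [
            (fid, i, r.path, r.vr, r.value, r.value_text)
            for i, r in enumerate(model.iter_element_rows(pds))
        ]
        cur.executemany(
            "INSERT INTO elements (file_id, ord, path, vr, value, value_text)"
            " VALUES (?,?,?,?,?,?)",
            rows,
        )
        return fid

    def _advance_head(
        self,
        cur: sqlite3.Cursor,
        subject: str,
        new_file_ids: Sequence[int],
        origin: str,
        replaced: Optional[dict[int, int]] = None,
        user: Optional[str] = None,
    ) -> int:
        """Create a revision = head's file set, with ``replaced`` old→new
        swaps applied and ``new_file_ids`` appended; move head to it."""
        head = self.head(subject)
        base: list[int] = []
        if head is not None:
            base = [
                r["file_id"]
                for r in cur.execute(
                    "SELECT file_id FROM revision_files WHERE revision_id=?"
                    " ORDER BY file_id",
                    (head,),
                )
            ]
        if replaced:
            base = [replaced.get(fid, fid) for fid in base]
        fileset = base + [f for f in new_file_ids if f not in base]
        cur.execute(
            "INSERT INTO revisions (subject, parent, created, user, origin)"
            " VALUES (?,?,?,?,?)",
            (subject, head, _now(), user or self.user, origin),
        )
        rev = cur.lastrowid
        cur.executemany(
            "INSERT INTO revision_files (revision_id, file_id) VALUES (?,?)",
            [(rev, fid) for fid in fileset],
        )
        cur.execute(
            "INSERT INTO heads (subject, revision_id) VALUES (?,?)"
            " ON CONFLICT(subject) DO UPDATE SET revision_id=excluded.revision_id",
            (subject, rev),
        )
        return rev

    # -- nicknames --------------------------------------------------------

    _NICK_FORMATS = {"file": "F{:06d}", "series": "SE{:04d}", "study": "ST{:02d}"}

    def _next_nickname(self, cur: sqlite3.Cursor, subject: str, kind: str) -> str:
        n = cur.execute(
            "SELECT COUNT(*) c FROM nicknames WHERE scope_subject=? AND kind=?",
            (subject, kind),
        ).fetchone()["c"]
        return self._NICK_FORMATS[kind].format(n + 1)

    def assign_nicknames(self, subject: str) -> dict[str, dict[str, str]]:
        """Ensure every file, series and study under the subject has exactly
        one nickname; returns ``{kind: {target: nickname}}``.  Repeated calls
        return the identical map; new entities extend the counters without
        disturbing existing assignments."""
        cur = self._conn.cursor()
        files = cur.execute(
            "SELECT file_id, study_uid, series_uid FROM files WHERE subject=?"
            " ORDER BY file_id",
            (subject,),
        ).fetchall()
        if not files:
            raise UnknownSubject(subject)
        for kind, key in (("study", "study_uid"), ("series", "series_uid")):
            seen = []
            for row in files:
                uid = row[key]
                if uid is not None and uid not in seen:
                    seen.append(uid)
            for uid in seen:
                exists = cur.execute(
                    "SELECT 1 FROM nicknames WHERE scope_subject=? AND kind=?"
                    " AND target=?",
                    (subject, kind, uid),
                ).fetchone()
                if exists is None:
                    cur.execute(
                        "INSERT INTO nicknames (scope_subject, kind, nickname,"
                        " target) VALUES (?,?,?,?)",
                        (subject, kind, self._next_nickname(cur, subject, kind), uid),
                    )
        self._conn.commit()
        out: dict[str, dict[str, str]] = {"file": {}, "series": {}, "study": {}}
        for row in cur.execute(
            "SELECT kind, nickname, target FROM nicknames WHERE scope_subject=?",
            (subject,),
        ):
            out[row["kind"]][row["target"]] = row["nickname"]
        return out

    def resolve_nickname(self, subject: str, nickname: str) -> Optional[str]:
        row = self._conn.execute(
            "SELECT target FROM nicknames WHERE scope_subject=? AND nickname=?",
            (subject, nickname),
        ).fetchone()
        return row["target"] if row else None

    # -- revisions / heads ------------------------------------------------

    def head(self, subject: str) -> Optional[int]:
        row = self._conn.execute(
            "SELECT revision_id FROM heads WHERE subject=?", (subject,)
        ).fetchone()
        return row["revision_id"] if row else None

    def revision(self, revision_id: int) -> sqlite3.Row:
        row = self._conn.execute(
            "SELECT * FROM revisions WHERE revision_id=?", (revision_id,)
        ).fetchone()
        if row is None:
            raise RevisionNotFound(str(revision_id))
        return row

    def revision_file_rows(self, revision_id: int) -> list[sqlite3.Row]:
        self.revision(revision_id)
        return self._conn.execute(
            "SELECT f.* FROM revision_files rf JOIN files f USING (file_id)"
            " WHERE rf.revision_id=? ORDER BY f.file_id",
            (revision_id,),
        ).fetchall()

    def head_file_rows(self, subject: str) -> list[sqlite3.Row]:
        head = self.head(subject)
        if head is None:
            raise UnknownSubject(subject)
        return self.revision_file_rows(head)

    def subjects(self, collection: Optional[str] = None) -> list[str]:
        if collection is None:
            rows = self._conn.execute(
                "SELECT subject FROM subjects ORDER BY subject"
            ).fetchall()
        else:
            rows = self._conn.execute(
                "SELECT subject FROM subjects WHERE collection=? ORDER BY subject",
                (collection,),
            ).fetchall()
        return [r["subject"] for r in rows]

    def scope_file_rows(
        self, collection: Optional[str] = None, subject: Optional[str] = None
    ) -> list[sqlite3.Row]:
        """Head file rows of one subject, one collection, or the whole
        workspace."""
        if subject is not None:
            return self.head_file_rows(subject)
        rows: list[sqlite3.Row] = []
        for subj in self.subjects(collection):
            if self.head(subj) is not None:
                rows.extend(self.head_file_rows(subj))
        return rows

    # -- element value queries -------------------------------------------

    def element_values(
        self, file_ids: Sequence[int], tag: Union[str, Tag]
    ) -> dict[int, Optional[bytes]]:
        """Top-level element value bytes per file; ``None`` marks absence
        (distinct from ``b""``, a present-but-empty value)."""
        tag = tag if isinstance(tag, Tag) else Tag.parse(str(tag))
        out: dict[int, Optional[bytes]] = {fid: None for fid in file_ids}
        if not file_ids:
            return out
        marks = ",".join("?" * len(file_ids))
        for row in self._conn.execute(
            f"SELECT file_id, value FROM elements WHERE path=? AND file_id IN ({marks})",
            (tag.render(), *file_ids),
        ):
            out[row["file_id"]] = row["value"] if row["value"] is not None else b""
        return out

    def query_entity_attribute_values(
        self,
        level: str,
        tag: Union[str, Tag],
        collection: Optional[str] = None,
        subject: Optional[str] = None,
    ) -> list[tuple[Optional[str], Optional[str], int]]:
        """Distinct (entity, value) pairs with file counts.

        ``value`` is the pad-stripped text, ``None`` for absent (rendered as
        a distinguished ``ABSENT`` bucket in reports, distinct from ``""``).
        """
        key = {"patient": "patient_id", "study": "study_uid", "series": "series_uid"}[
            level
        ]
        files = self.scope_file_rows(collection, subject)
        values = self.element_values([f["file_id"] for f in files], tag)
        counts: dict[tuple, int] = {}
        for f in files:
            vb = values[f["file_id"]]
            value = (
                None
                if vb is None
                else model.strip_pad(vb).decode("ascii", "replace")
            )
            k = (f[key], value)
            counts[k] = counts.get(k, 0) + 1
        return sorted(
            [(e, v, c) for (e, v), c in counts.items()],
            key=lambda t: (t[0] or "", t[1] is None, t[1] or ""),
        )

    # -- digests ----------------------------------------------------------

    def digest_histogram(
        self, collection: Optional[str] = None, subject: Optional[str] = None
    ) -> dict[int, int]:
        """``{multiplicity m: number of distinct pixel digests occurring in
        exactly m files}`` over the scope's head files; files without pixels
        are excluded."""
        counts: dict[str, int] = {}
        for f in self.scope_file_rows(collection, subject):
            d = f["pixel_digest"]
            if d != NO_PIXELS:
                counts[d] = counts.get(d, 0) + 1
        hist: dict[int, int] = {}
        for c in counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist

    def blocklist_digest(self, pixel_digest: str, note: str = "") -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO digest_blocklist (pixel_digest, note)"
            " VALUES (?,?)",
            (pixel_digest, note),
        )
        self._conn.commit()

    def blocklisted(self, pixel_digest: str) -> bool:
        return (
            self._conn.execute(
                "SELECT 1 FROM digest_blocklist WHERE pixel_digest=?",
                (pixel_digest,),
            ).fetchone()
            is not None
        )

    # -- export -----------------------------------------------------------

    def export_head(self, subject: str, out_dir: Union[str, Path]) -> list[Path]:
        """Write the subject's current head file set to a directory, one
        file per record, named by nickname."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for row in self.head_file_rows(subject):
            dest = out / f"{row['nickname']}.dcm"
            dest.write_bytes(self.read_object(row["file_digest"]))
            written.append(dest)
        return written


def _z_offset(pds: ParsedDataset) -> Optional[float]:
    # third component of Image Position (Patient), falling back to Slice
    # Location; absent means the file cannot take part in offset alignment
    ipp = model.top_level_text(pds.dataset, Tag(0x0020, 0x0032))
    if ipp:
        parts = ipp.split("\\")
        if len(parts) >= 3:
            try:
                return float(parts[2])
            except ValueError:
                pass
    sl = model.top_level_text(pds.dataset, Tag(0x0020, 0x1041))
    if sl:
        try:
            return float(sl)
        except ValueError:
            return None
    return None


def _int_or_none(text: Optional[str]) -> Optional[int]:
    if not text:
        return None
    try:
        return int(text.strip())
    except ValueError:
        return None
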