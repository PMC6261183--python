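"""Duplicate pixel-data analysis and proto-series inference.

Because the intake database stores an MD5 digest of every image's pixel
payload, duplicated pixel data — even under fresh UIDs from repeated
de-identification — reduces to grouping digests.  The analysis ladder:

1. *digest groups*: digests occurring in >= m files;
2. *distinguished digests*: blank images, test patterns and user-listed
   digests whose many duplicates are expected and uninformative;
3. *candidate duplicate series*: sets of series that jointly contain many
   digests of one multiplicity;
4. *series comparison*: shared-digest counts plus the constant z-offset
   shift between two series, when one exists;
5. *proto-series inference*: align a connected set of overlapping series
   into a common frame and reconstruct the original ("proto") series they
   were all cut from.

The z-offset of a slice is the third component of Image Position (Patient),
falling back to Slice Location; files without either still count for digest
multiplicity but sit out the offset alignment.  Offsets are decimal strings
in DICOM, so alignment uses a tight tolerance (1e-3 mm) and offsets are
rounded to six decimals.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .db import Workspace
from .errors import DisconnectedSet, InconsistentShift
from .model import NO_PIXELS, PIXEL_DATA_TAG, parse_bytes

ALIGNMENT_TOLERANCE_MM = 1e-3
OFFSET_DECIMALS = 6

#: a digest is flagged as a probable test pattern / shared artifact when it
#: reaches both thresholds
DISTINGUISHED_MIN_FILES = 50
DISTINGUISHED_MIN_SUBJECTS = 10


@dataclass
class DigestGroup:
    pixel_digest: str
    files: list[dict]  # collection, site, subject, series_uid, nickname, z_offset
    distinguished: Optional[str] = None  # blank | test_pattern | manual | None

    @property
    def file_count(self) -> int:
        return len(self.files)

    @property
    def subjects(self) -> set:
        return {f["subject"] for f in self.files}

    @property
    def series(self) -> frozenset:
        return frozenset(f["series_uid"] for f in self.files)

    def to_dict(self) -> dict:
        return {
            "pixel_digest": self.pixel_digest,
            "file_count": self.file_count,
            "distinguished": self.distinguished,
            "files": self.files,
        }


@dataclass
class SeriesComparison:
    series_a: str
    series_b: str
    a_total: int
    b_total: int
    shared_digest_count: int
    a_only: int
    b_only: int
    offset_shift: Optional[float]  # b minus a, millimetres
    shift_consistent: bool

    def to_dict(self) -> dict:
        return {
            "series_a": self.series_a,
            "series_b": self.series_b,
            "a_total": self.a_total,
            "b_total": self.b_total,
            "shared_digest_count": self.shared_digest_count,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "offset_shift": self.offset_shift,
            "shift_consistent": self.shift_consistent,
        }


@dataclass
class ProtoImage:
    pixel_digest: str
    offset: Optional[float]  # inferred position in the anchor frame
    membership: dict  # series_uid -> local offset (or None)


@dataclass
class ProtoSeries:
    """The inferred original series behind a set of overlapping copies."""

    images: list[ProtoImage]
    anchor_series: str
    series_order: list[str]
    non_contiguous_series: list[str] = field(default_factory=list)

    @property
    def offsets(self) -> list[Optional[float]]:
        return [im.offset for im in self.images]

    def series_run(self, series_uid: str) -> list[int]:
        return [
            i for i, im in enumerate(self.images) if series_uid in im.membership
        ]

    def to_dict(self) -> dict:
        return {
            "anchor_series": self.anchor_series,
            "image_count": len(self.images),
            "series": self.series_order,
            "non_contiguous_series": self.non_contiguous_series,
            "images": [
                {
                    "pixel_digest": im.pixel_digest,
                    "offset": im.offset,
                    "membership": im.membership,
                }
                for im in self.images
            ],
        }


# ---------------------------------------------------------------------------
# digest groups


def find_duplicate_digest_groups(
    ws: Workspace,
    min_count: int = 2,
    collection: Optional[str] = None,
    subject: Optional[str] = None,
    classify: bool = True,
) -> list[DigestGroup]:
    """Digest groups with >= ``min_count`` files, largest first; files
    without pixel data are excluded."""
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    sites = _site_map(ws)
    by_digest: dict[str, list[dict]] = defaultdict(list)
    for row in ws.scope_file_rows(collection, subject):
        if row["pixel_digest"] == NO_PIXELS:
            continue
        by_digest[row["pixel_digest"]].append(
            {
                "collection": row["collection"],
                "site": sites.get(row["subject"]),
                "subject": row["subject"],
                "series_uid": row["series_uid"],
                "nickname": row["nickname"],
                "z_offset": row["z_offset"],
            }
        )
    groups = [
        DigestGroup(pixel_digest=d, files=sorted(fs, key=lambda f: f["nickname"]))
        for d, fs in by_digest.items()
        if len(fs) >= min_count
    ]
    groups.sort(key=lambda g: (-g.file_count, g.pixel_digest))
    if classify:
        for g in groups:
            g.distinguished = classify_distinguished(ws, g)
    return groups


def _site_map(ws: Workspace) -> dict:
    return {
        r["subject"]: r["site"]
        for r in ws.conn.execute("SELECT subject, site FROM subjects")
    }


def classify_distinguished(ws: Workspace, group: DigestGroup) -> Optional[str]:
    """``manual`` for blocklisted digests, ``blank`` for single-repeated-byte
    payloads, ``test_pattern`` for the high-multiplicity many-subject
    heuristic, else ``None``."""
    if not group.files:
        raise ValueError("empty digest group")
    if ws.blocklisted(group.pixel_digest):
        return "manual"
    if _is_blank_payload(ws, group):
        return "blank"
    if (
        group.file_count >= DISTINGUISHED_MIN_FILES
        and len(group.subjects) >= DISTINGUISHED_MIN_SUBJECTS
    ):
        return "test_pattern"
    return None


def _is_blank_payload(ws: Workspace, group: DigestGroup) -> bool:
    nickname = group.files[0]["nickname"]
    subject = group.files[0]["subject"]
    row = ws.conn.execute(
        "SELECT file_digest FROM files WHERE subject=? AND nickname=?"
        " ORDER BY file_id DESC LIMIT 1",
        (subject, nickname),
    ).fetchone()
    if row is None:
        return False
    pds = parse_bytes(ws.read_object(row["file_digest"]))
    elem = pds.dataset.get_item(PIXEL_DATA_TAG)
    payload = bytes(getattr(elem, "value", b"") or b"")
    return len(set(payload)) == 1 if payload else False


# ---------------------------------------------------------------------------
# candidate duplicate series


@dataclass
class CandidateSeriesSet:
    series: tuple[str, ...]  # sorted series UIDs
    digest_count: int
    subjects: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "series": list(self.series),
            "subjects": list(self.subjects),
            "digest_count": self.digest_count,
        }


def find_candidate_duplicate_series(
    ws: Workspace,
    multiplicity: int,
    collection: Optional[str] = None,
    subject: Optional[str] = None,
) -> list[CandidateSeriesSet]:
    """Group the digests occurring in exactly ``multiplicity`` files by the
    set of series containing them; each set of series sharing such digests
    is one candidate, largest digest count first.  Distinguished digests
    are excluded."""
    groups = find_duplicate_digest_groups(
        ws, min_count=2, collection=collection, subject=subject
    )
    buckets: dict[frozenset, list[DigestGroup]] = defaultdict(list)
    for g in groups:
        if g.distinguished is not None:
            continue
        if g.file_count == multiplicity:
            buckets[g.series].append(g)
    out = []
    for series_set, gs in buckets.items():
        subjects = sorted({f["subject"] for g in gs for f in g.files})
        out.append(
            CandidateSeriesSet(
                series=tuple(sorted(series_set)),
                digest_count=len(gs),
                subjects=tuple(subjects),
            )
        )
    out.sort(key=lambda c: (-c.digest_count, c.series))
    return out


# ---------------------------------------------------------------------------
# series comparison and proto inference (record-level core)

SeriesRecord = tuple[str, list[tuple[str, Optional[float]]]]
"""(series_uid, [(pixel_digest, z_offset-or-None), ...])"""


def series_records(ws: Workspace, series_uids: Sequence[str]) -> list[SeriesRecord]:
    rows = ws.conn.execute(
        "SELECT subject FROM files GROUP BY subject"
    ).fetchall()
    wanted = set(series_uids)
    per_series: dict[str, list] = {uid: [] for uid in series_uids}
    for r in rows:
        subj = r["subject"]
        if ws.head(subj) is None:
            continue
        for f in ws.head_file_rows(subj):
            if f["series_uid"] in wanted and f["pixel_digest"] != NO_PIXELS:
                per_series[f["series_uid"]].append(
                    (f["pixel_digest"], f["z_offset"])
                )
    missing = [uid for uid, files in per_series.items() if not files]
    if missing:
        raise DisconnectedSet(f"series not found in workspace: {missing}")
    return [(uid, per_series[uid]) for uid in series_uids]


def compare_records(a: SeriesRecord, b: SeriesRecord) -> SeriesComparison:
    uid_a, files_a = a
    uid_b, files_b = b
    off_a = {d: z for d, z in files_a}
    off_b = {d: z for d, z in files_b}
    set_a, set_b = set(off_a), set(off_b)
    shared = set_a & set_b
    shifts = [
        off_b[d] - off_a[d]
        for d in shared
        if off_a[d] is not None and off_b[d] is not None
    ]
    shift: Optional[float] = None
    consistent = False
    if shifts:
        if max(shifts) - min(shifts) <= ALIGNMENT_TOLERANCE_MM:
            shift = round(sum(shifts) / len(shifts), OFFSET_DECIMALS)
            consistent = True
    return SeriesComparison(
        series_a=uid_a,
        series_b=uid_b,
        a_total=len(set_a),
        b_total=len(set_b),
        shared_digest_count=len(shared),
        a_only=len(set_a - set_b),
        b_only=len(set_b - set_a),
        offset_shift=shift,
        shift_consistent=consistent,
    )


def compare_series(ws: Workspace, series_a: str, series_b: str) -> SeriesComparison:
    recs = series_records(ws, [series_a, series_b])
    return compare_records(recs[0], recs[1])


def infer_proto_from_records(records: Sequence[SeriesRecord]) -> ProtoSeries:
    """Reconstruct the proto series from overlapping series records.

    Pairs sharing >= 2 positioned digests must shift consistently (else
    :class:`InconsistentShift`); the pairwise graph must be connected (else
    :class:`DisconnectedSet`).  The anchor is the series containing the
    image at the top of the aligned stack — the series whose local offsets
    need no renumbering — with ties broken by image count, then UID.
    """
    if not records:
        raise DisconnectedSet("no series given")
    uids = [uid for uid, _ in records]
    if len(uids) == 1:
        return _single_series_proto(records[0])

    # pairwise consistent shifts
    edges: dict[tuple[str, str], float] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            cmp = compare_records(records[i], records[j])
            if cmp.shared_digest_count >= 2:
                if not cmp.shift_consistent:
                    raise InconsistentShift(
                        f"{cmp.series_a} vs {cmp.series_b}: offsets disagree"
                    )
                edges[(cmp.series_a, cmp.series_b)] = cmp.offset_shift

    # breadth-first accumulation of per-series frame positions:
    # aligned = local + pos[uid]
    adj: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for (a, b), shift in edges.items():
        adj[a].append((b, shift))
        adj[b].append((a, -shift))
    pos = {uids[0]: 0.0}
    queue = [uids[0]]
    while queue:
        cur = queue.pop(0)
        for nb, shift in adj[cur]:
            cand = pos[cur] - shift
            if nb in pos:
                if abs(pos[nb] - cand) > ALIGNMENT_TOLERANCE_MM:
                    raise InconsistentShift(
                        f"cycle through {nb} closes with mismatched shift"
                    )
            else:
                pos[nb] = cand
                queue.append(nb)
    if set(pos) != set(uids):
        raise DisconnectedSet(
            f"series cannot be aligned: {sorted(set(uids) - set(pos))}"
        )

    # union of images in a provisional frame
    aligned: dict[str, dict] = {}
    for uid, files in records:
        for digest, z in files:
            a = None if z is None else round(z + pos[uid], OFFSET_DECIMALS)
            entry = aligned.setdefault(
                digest, {"offset": a, "membership": {}}
            )
            entry["membership"][uid] = z
            if entry["offset"] is None:
                entry["offset"] = a
            elif a is not None and abs(entry["offset"] - a) > ALIGNMENT_TOLERANCE_MM:
                raise InconsistentShift(
                    f"digest {digest} lands at both {entry['offset']} and {a}"
                )

    # anchor = series holding the topmost aligned image
    top = max(
        (e["offset"] for e in aligned.values() if e["offset"] is not None),
        default=None,
    )
    if top is None:
        raise InconsistentShift("no positioned images to align")
    holders = {
        uid
        for e in aligned.values()
        if e["offset"] is not None and abs(e["offset"] - top) <= ALIGNMENT_TOLERANCE_MM
        for uid in e["membership"]
    }
    sizes = {uid: len(files) for uid, files in records}
    anchor = min(holders, key=lambda u: (-sizes[u], u))

    # re-base so the anchor's local offsets are the proto offsets
    base = pos[anchor]
    images = []
    for digest, e in aligned.items():
        off = (
            None
            if e["offset"] is None
            else round(e["offset"] - base, OFFSET_DECIMALS)
        )
        images.append(ProtoImage(digest, off, e["membership"]))
    images.sort(key=lambda im: (im.offset is None, im.offset or 0.0, im.pixel_digest))

    proto = ProtoSeries(images=images, anchor_series=anchor, series_order=list(uids))
    positioned = [im for im in images if im.offset is not None]
    for uid in uids:
        idxs = [i for i, im in enumerate(positioned) if uid in im.membership]
        if idxs and idxs != list(range(idxs[0], idxs[-1] + 1)):
            proto.non_contiguous_series.append(uid)
    return proto


def _single_series_proto(record: SeriesRecord) -> ProtoSeries:
    uid, files = record
    images = [ProtoImage(d, z, {uid: z}) for d, z in files]
    images.sort(key=lambda im: (im.offset is None, im.offset or 0.0, im.pixel_digest))
    return ProtoSeries(images=images, anchor_series=uid, series_order=[uid])


def infer_proto_series(ws: Workspace, series_uids: Sequence[str]) -> ProtoSeries:
    return infer_proto_from_records(series_records(ws, series_uids))
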