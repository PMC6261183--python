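"""Entity-consistency diagnosis and automatic bulk-edit proposals.

A DICOM entity (patient, study, series) is consistent for an attribute when
every file of the entity carries the same value.  The checker buckets files
by raw value bytes (stripping only the single DICOM pad byte — no
transcoding or normalization, so real clashes are never hidden) with
absence as its own bucket, and reports a finding whenever an entity shows
two or more buckets for a checked attribute.

Findings can be turned into proposed edits under three policies:

``majority``
    the most frequent non-absent value wins; ties break to the
    lexicographically smallest value.
``first_file``
    the value of the entity's first file (lowest instance number, then
    import order) is propagated to the rest — the classic repair for
    per-slice Frame of Reference UIDs.
``manual``
    a proposal with the chosen value left blank for the user.

Proposals are never auto-applied; they start in status ``proposed`` and are
handed to the revision manager explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import yaml

from .db import Workspace
from .errors import NoNonAbsentValue
from .model import Tag, strip_pad

#: entity-level attributes checked by default; override via a ruleset file
DEFAULT_RULESET_TAGS = {
    "patient": ["0010,0010", "0010,0020", "0010,0030", "0010,0040", "0010,1030"],
    "study": ["0008,0020", "0008,0030", "0008,1030", "0008,0050"],
    "series": ["0008,0060", "0008,103E", "0020,0052", "0018,0015", "0008,0021"],
}

_LEVEL_KEY = {"patient": "patient_id", "study": "study_uid", "series": "series_uid"}


@dataclass(frozen=True)
class ConsistencyRuleset:
    patient: tuple[Tag, ...]
    study: tuple[Tag, ...]
    series: tuple[Tag, ...]

    def tags_for(self, level: str) -> tuple[Tag, ...]:
        return getattr(self, level)

    @classmethod
    def from_dict(cls, data: dict) -> "ConsistencyRuleset":
        return cls(
            patient=tuple(Tag.parse(t) for t in data.get("patient", [])),
            study=tuple(Tag.parse(t) for t in data.get("study", [])),
            series=tuple(Tag.parse(t) for t in data.get("series", [])),
        )

    @classmethod
    def default(cls) -> "ConsistencyRuleset":
        return cls.from_dict(DEFAULT_RULESET_TAGS)

    @classmethod
    def from_yaml(cls, path) -> "ConsistencyRuleset":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Bucket:
    """One observed value (``None`` = absent) with its supporting files."""

    value: Optional[str]
    file_count: int
    nicknames: list[str]

    def to_dict(self) -> dict:
        return {
            "value": "ABSENT" if self.value is None else self.value,
            "file_count": self.file_count,
            "files": self.nicknames,
        }


@dataclass
class InconsistencyFinding:
    level: str
    entity_id: Optional[str]
    subject: str
    tag: Tag
    buckets: list[Bucket]
    per_file_descriptions: bool = False

    @property
    def file_count(self) -> int:
        return sum(b.file_count for b in self.buckets)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "entity_id": self.entity_id,
            "subject": self.subject,
            "tag": self.tag.render(),
            "per_file_descriptions": self.per_file_descriptions,
            "buckets": [b.to_dict() for b in self.buckets],
        }


@dataclass
class ProposedEdit:
    """A candidate repair for one finding; never applied automatically."""

    subject: str
    level: str
    entity_id: Optional[str]
    tag: Tag
    action: str  # "set" | "delete"
    chosen_value: Optional[str]
    policy_used: str
    targets: list[str]  # file nicknames to rewrite
    status: str = "proposed"

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "level": self.level,
            "entity_id": self.entity_id,
            "tag": self.tag.render(),
            "action": self.action,
            "chosen_value": self.chosen_value,
            "policy_used": self.policy_used,
            "targets": self.targets,
            "status": self.status,
        }


def check_entity(
    ws: Workspace,
    level: str,
    entity_id: Optional[str],
    file_rows: Sequence,
    ruleset: Optional[ConsistencyRuleset] = None,
) -> list[InconsistencyFinding]:
    """Findings for one entity's files: one per checked tag showing >= 2
    distinct value buckets (absence counts as a bucket), in tag order."""
    ruleset = ruleset or ConsistencyRuleset.default()
    findings = []
    file_ids = [f["file_id"] for f in file_rows]
    subject = file_rows[0]["subject"] if file_rows else ""
    for tag in sorted(ruleset.tags_for(level)):
        values = ws.element_values(file_ids, tag)
        buckets: dict[Optional[bytes], list] = {}
        for f in file_rows:
            vb = values[f["file_id"]]
            key = strip_pad(vb) if vb is not None else None
            buckets.setdefault(key, []).append(f["nickname"])
        if len(buckets) < 2:
            continue
        blist = [
            Bucket(
                value=None if k is None else k.decode("ascii", "replace"),
                file_count=len(nicks),
                nicknames=sorted(nicks),
            )
            for k, nicks in buckets.items()
        ]
        blist.sort(key=lambda b: (b.value is None, b.value or "", -b.file_count))
        findings.append(
            InconsistencyFinding(
                level=level,
                entity_id=entity_id,
                subject=subject,
                tag=tag,
                buckets=blist,
                per_file_descriptions=(
                    len(blist) == len(file_rows) and len(file_rows) >= 2
                ),
            )
        )
    return findings


def scan_subject(
    ws: Workspace, subject: str, ruleset: Optional[ConsistencyRuleset] = None
) -> list[InconsistencyFinding]:
    ruleset = ruleset or ConsistencyRuleset.default()
    rows = ws.head_file_rows(subject)
    findings: list[InconsistencyFinding] = []
    for level in ("patient", "study", "series"):
        key = _LEVEL_KEY[level]
        groups: dict[Optional[str], list] = {}
        for row in rows:
            groups.setdefault(row[key], []).append(row)
        for entity_id in sorted(groups, key=lambda e: (e is None, e or "")):
            findings.extend(
                check_entity(ws, level, entity_id, groups[entity_id], ruleset)
            )
    return findings


def scan_collection(
    ws: Workspace,
    collection: Optional[str] = None,
    ruleset: Optional[ConsistencyRuleset] = None,
) -> dict[str, list[InconsistencyFinding]]:
    """Scan all subjects at once; subjects with no findings are omitted."""
    out: dict[str, list[InconsistencyFinding]] = {}
    for subject in ws.subjects(collection):
        if ws.head(subject) is None:
            continue
        findings = scan_subject(ws, subject, ruleset)
        if findings:
            out[subject] = findings
    return out


def report_dict(findings_by_subject: dict[str, list[InconsistencyFinding]]) -> dict:
    return {
        "finding_count": sum(len(v) for v in findings_by_subject.values()),
        "subjects": {
            s: [f.to_dict() for f in fs] for s, fs in findings_by_subject.items()
        },
    }


def report_csv_rows(
    findings_by_subject: dict[str, list[InconsistencyFinding]]
) -> list[dict]:
    """Flat consistency-check rows: one per (finding, bucket)."""
    rows = []
    for subject, findings in findings_by_subject.items():
        for f in findings:
            for b in f.buckets:
                rows.append(
                    {
                        "subject": subject,
                        "level": f.level,
                        "entity_id": f.entity_id,
                        "tag": f.tag.render(),
                        "value": "ABSENT" if b.value is None else b.value,
                        "file_count": b.file_count,
                        "files": " ".join(b.nicknames),
                    }
                )
    return rows


def propose_fixes(
    ws: Workspace,
    findings: Sequence[InconsistencyFinding],
    policy: str = "majority",
) -> list[ProposedEdit]:
    """One proposed edit per finding; see the module docstring for
    policies.  Raises :class:`NoNonAbsentValue` under ``majority`` when no
    bucket carries a value."""
    if policy not in ("majority", "first_file", "manual"):
        raise ValueError(f"unknown policy {policy!r}")
    edits = []
    for finding in findings:
        if policy == "manual":
            targets = sorted(
                n for b in finding.buckets for n in b.nicknames
            )
            edits.append(
                ProposedEdit(
                    subject=finding.subject,
                    level=finding.level,
                    entity_id=finding.entity_id,
                    tag=finding.tag,
                    action="set",
                    chosen_value=None,
                    policy_used="manual",
                    targets=targets,
                )
            )
            continue
        if policy == "majority":
            candidates = [b for b in finding.buckets if b.value is not None]
            if not candidates:
                raise NoNonAbsentValue(
                    f"{finding.subject}/{finding.tag}: all buckets absent"
                )
            best = min(candidates, key=lambda b: (-b.file_count, b.value))
            chosen, action = best.value, "set"
        else:  # first_file
            first = _first_file_nickname(ws, finding)
            holder = next(
                b for b in finding.buckets if first in b.nicknames
            )
            chosen = holder.value
            action = "set" if chosen is not None else "delete"
        targets = sorted(
            n
            for b in finding.buckets
            if b.value != chosen
            for n in b.nicknames
        )
        edits.append(
            ProposedEdit(
                subject=finding.subject,
                level=finding.level,
                entity_id=finding.entity_id,
                tag=finding.tag,
                action=action,
                chosen_value=chosen,
                policy_used=policy,
                targets=targets,
            )
        )
    return edits


def _first_file_nickname(ws: Workspace, finding: InconsistencyFinding) -> str:
    nicks = {n for b in finding.buckets for n in b.nicknames}
    rows = [
        r for r in ws.head_file_rows(finding.subject) if r["nickname"] in nicks
    ]
    rows.sort(
        key=lambda r: (
            r["instance_number"] is None,
            r["instance_number"] if r["instance_number"] is not None else 0,
            r["file_id"],
        )
    )
    return rows[0]["nickname"]


def apply_proposed(ws: Workspace, edits: Sequence[ProposedEdit]) -> list[int]:
    """Apply approved proposals through the revision manager, one revision
    per edit; returns the new revision ids."""
    from . import revisions as _rev

    created = []
    for edit in edits:
        if edit.chosen_value is None and edit.action == "set":
            raise NoNonAbsentValue("manual proposal not completed")
        spec = _rev.EditSpecification(
            subject=edit.subject,
            targets=list(edit.targets),
            operations=[
                _rev.EditOperation(
                    path=edit.tag.render(),
                    action=edit.action,
                    value=edit.chosen_value,
                )
            ],
            origin=f"consistency-fix:{edit.policy_used}:{edit.tag.render()}",
            user=ws.user,
        )
        handle = _rev.begin_edit(ws, edit.subject)
        rev = _rev.apply_edit(handle, spec)
        created.append(rev.revision_id)
        edit.status = "approved"
    return created
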