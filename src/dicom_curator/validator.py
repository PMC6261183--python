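"""Wrapper around an external per-file DICOM conformance validator.

The toolkit does not re-implement IOD validation; it runs an external
checker (conventionally ``dciodvfy`` from dicom3tools) on the *first file
of every series* — lowest Instance Number, ties by SOP Instance UID — and
turns its verbose per-file output into a clustered report: series are
partitioned by their exact set of normalized findings, so a handful of
clusters summarizes thousands of lines, and every finding stays attached
to the series (and subject) it came from.

Normalization masks attribute values, UIDs and file paths but keeps the
message skeleton and tag numbers, so the same problem reported against
different files clusters together.  Tests (and offline use) inject
pre-captured validator text with ``from_dir``; the external binary is
optional.
"""

from __future__ import annotations

import re
import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .db import Workspace
from .errors import CommandNotFound

_UID_RE = re.compile(r"\b\d+(?:\.\d+){3,}\b")
_PATH_RE = re.compile(r"(?:^|(?<=\s))/[^\s\"']+")
_QUOTED_RE = re.compile(r'"[^"]*"')


@dataclass(frozen=True)
class ValidatorFinding:
    severity: str  # "error" | "warning"
    message: str  # normalized text
    series_uid: str
    subject: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.severity, self.message)


@dataclass
class SeriesOutput:
    series_uid: str
    subject: str
    path: str
    text: str
    exit_code: int = 0


@dataclass
class FindingCluster:
    findings: tuple[tuple[str, str], ...]  # sorted (severity, message) set
    series: list[tuple[str, str]]  # (series_uid, subject)

    def to_dict(self) -> dict:
        return {
            "findings": [
                {"severity": s, "message": m} for s, m in self.findings
            ],
            "series_count": len(self.series),
            "series": [
                {"series_uid": u, "subject": s} for u, s in self.series
            ],
        }


def select_series_representatives(
    ws: Workspace,
    collection: Optional[str] = None,
    subject: Optional[str] = None,
) -> list[tuple[str, str, str]]:
    """Exactly one (series_uid, subject, stored path) per series: the file
    with the lowest Instance Number, ties (or missing numbers) resolved by
    lexicographically smallest SOP Instance UID."""
    best: dict[str, tuple] = {}
    for row in ws.scope_file_rows(collection, subject):
        uid = row["series_uid"]
        if uid is None:
            continue
        rank = (
            row["instance_number"] is None,
            row["instance_number"] if row["instance_number"] is not None else 0,
            row["sop_uid"] or "",
        )
        if uid not in best or rank < best[uid][0]:
            best[uid] = (rank, row)
    reps = [
        (uid, row["subject"], row["storage_path"])
        for uid, (_, row) in best.items()
    ]
    reps.sort()
    return reps


def normalize_message(raw: str) -> str:
    """Deterministic value-independent form of a validator line."""
    msg = _QUOTED_RE.sub('"<value>"', raw.strip())
    msg = _UID_RE.sub("<uid>", msg)
    msg = _PATH_RE.sub("<path>", msg)
    return re.sub(r"\s+", " ", msg)


def parse_output(out: SeriesOutput) -> list[ValidatorFinding]:
    """dciodvfy dialect: leading ``Error - `` / ``Warning - ``; anything
    else is kept verbatim as a warning."""
    findings = []
    for line in out.text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("Error - "):
            severity, body = "error", line[len("Error - "):]
        elif line.startswith("Warning - "):
            severity, body = "warning", line[len("Warning - "):]
        else:
            severity, body = "warning", line
        findings.append(
            ValidatorFinding(
                severity=severity,
                message=normalize_message(body),
                series_uid=out.series_uid,
                subject=out.subject,
            )
        )
    return findings


def run_validator(
    representatives: Sequence[tuple[str, str, str]],
    command_template: Optional[str] = None,
    from_dir: Optional[Union[str, Path]] = None,
) -> list[SeriesOutput]:
    """Collect raw validator output for every representative.

    ``command_template`` is a shell-ish template with a ``{file}``
    placeholder, run per file with stdout+stderr captured; a nonzero exit
    is recorded, not fatal.  ``from_dir`` supplies pre-captured text files
    named ``<series_uid>.txt`` instead (missing file = clean series).
    """
    outputs = []
    if from_dir is not None:
        cap = Path(from_dir)
        for series_uid, subject, path in representatives:
            f = cap / f"{series_uid}.txt"
            text = f.read_text() if f.exists() else ""
            outputs.append(SeriesOutput(series_uid, subject, path, text))
        return outputs
    if command_template is None:
        raise CommandNotFound("no validator command and no captured output")
    argv0 = shlex.split(command_template.replace("{file}", "x"))[0]
    if shutil.which(argv0) is None:
        raise CommandNotFound(argv0)
    for series_uid, subject, path in representatives:
        argv = [
            part.replace("{file}", path)
            for part in shlex.split(command_template)
        ]
        proc = subprocess.run(argv, capture_output=True, text=True)
        outputs.append(
            SeriesOutput(
                series_uid,
                subject,
                path,
                proc.stdout + proc.stderr,
                proc.returncode,
            )
        )
    return outputs


def cluster_findings(
    findings: Sequence[ValidatorFinding],
) -> tuple[list[FindingCluster], dict[tuple[str, str], int]]:
    """Partition series by their exact normalized finding set.

    Returns clusters (largest first) plus a summary mapping each distinct
    finding to the number of series reporting it.  Series without findings
    appear in no cluster.
    """
    per_series: dict[tuple[str, str], set] = {}
    for f in findings:
        per_series.setdefault((f.series_uid, f.subject), set()).add(f.key)
    by_set: dict[tuple, list] = {}
    for series, keys in per_series.items():
        if keys:
            by_set.setdefault(tuple(sorted(keys)), []).append(series)
    clusters = [
        FindingCluster(findings=ks, series=sorted(ss))
        for ks, ss in by_set.items()
    ]
    clusters.sort(key=lambda c: (-len(c.series), c.findings))
    summary: dict[tuple[str, str], int] = {}
    for c in clusters:
        for key in c.findings:
            summary[key] = summary.get(key, 0) + len(c.series)
    return clusters, summary


def report_dict(
    clusters: list[FindingCluster], summary: dict[tuple[str, str], int]
) -> dict:
    return {
        "summary": [
            {"severity": s, "message": m, "series_count": n}
            for (s, m), n in sorted(
                summary.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        "clusters": [c.to_dict() for c in clusters],
    }
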