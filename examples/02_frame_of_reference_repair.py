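"""Diagnose and repair per-slice Frame of Reference UIDs.

A classic archive defect: an over-eager de-identifier gave every CT slice
its own Frame of Reference UID, breaking volumetric reconstruction.  The
repair propagates the first file's UID to the rest of the series, through
an audited revision that can be rolled back.
"""

import tempfile
from pathlib import Path

from dicom_curator import consistency as cons
from dicom_curator import fixtures as fx
from dicom_curator import revisions as rev
from dicom_curator.db import Workspace

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    paths = fx.generate_series(fx.SeriesSpec(n_images=6), seed=2, out_dir=tmp / "s1")
    fx.plant_unique_values(paths, "0020,0052", "1.9.")  # per-slice FoR UIDs

    ws = Workspace(tmp / "ws")
    ws.import_files(paths, "DEMO", "P1")
    ws.assign_nicknames("P1")
    root = ws.head("P1")

    findings = cons.scan_collection(ws)
    for f in findings["P1"]:
        print(f"finding: {f.level} {f.tag} with {len(f.buckets)} value buckets")

    edits = cons.propose_fixes(ws, findings["P1"], policy="first_file")
    for e in edits:
        print(f"proposal: set {e.tag} = {e.chosen_value} on {len(e.targets)} files")

    cons.apply_proposed(ws, edits)
    print("findings after repair:", cons.scan_collection(ws))  # {} = clean

    d = rev.diff(ws, "P1", root, ws.head("P1"))
    print(f"revision diff touches {sum(1 for f in d.files if not f.empty)} files")

    rev.rollback(ws, "P1", root)
    print("rolled back; findings again:",
          sum(len(v) for v in cons.scan_collection(ws).values()))
    # 1 — the defect is back, byte-identical to the import state.
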