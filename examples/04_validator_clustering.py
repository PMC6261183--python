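"""Cluster external-validator output across the series of a collection.

A conformance validator such as dciodvfy prints verbose per-file text.  Run
on the first file of every series and clustered by exact finding set, a
collection-wide report collapses to a few reviewable groups.  Here the
validator output is injected from captured text, as offline use (and the
test suite) does.
"""

import tempfile
from pathlib import Path

from dicom_curator import fixtures as fx
from dicom_curator import validator as val
from dicom_curator.db import Workspace

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    ws = Workspace(tmp / "ws")
    for k in range(1, 6):
        spec = fx.SeriesSpec(n_images=3, series_number=k, patient_id=f"P{k}")
        ws.import_files(
            fx.generate_series(spec, seed=k, out_dir=tmp / f"s{k}"), "DEMO", f"P{k}"
        )

    reps = val.select_series_representatives(ws)
    print(f"{len(reps)} series representatives (lowest instance number each)")

    # captured validator text: three series share one error, two have an extra
    capture = tmp / "capture"
    capture.mkdir()
    for i, (uid, _, _) in enumerate(reps):
        text = "Error - Missing attribute Type 1 Required Element=<BodyPartThickness>\n"
        if i >= 3:
            text += "Warning - Unrecognized defined term <ABDOMEN> for value\n"
        (capture / f"{uid}.txt").write_text(text)

    outputs = val.run_validator(reps, from_dir=capture)
    findings = [f for o in outputs for f in val.parse_output(o)]
    clusters, summary = val.cluster_findings(findings)

    for (sev, msg), n in summary.items():
        print(f"summary: [{sev}] {msg} -> {n} series")
    for c in clusters:
        print(f"cluster of {len(c.series)} series with {len(c.findings)} finding(s)")
    # two clusters partition the five series: {error}:3 and {error,warning}:2.
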