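"""Shared fixtures: all test data is generated, nothing is downloaded.

The three-series overlap workspace is expensive (581 files) and read-only
for every test that uses it, so it is built once per session.
"""

from pathlib import Path

import pytest

from dicom_curator import fixtures as fx
from dicom_curator.db import Workspace

FIG8_SEED = 1


@pytest.fixture(scope="session")
def fig8(tmp_path_factory):
    """(workspace, manifest) for the worked three-series duplicate example.

    Treat as read-only: tests that edit must build their own workspace.
    """
    root = tmp_path_factory.mktemp("fig8")
    manifest = fx.build_fig8_fixture(FIG8_SEED, root / "data")
    ws = Workspace(root / "ws")
    for series in manifest["series"]:
        files = sorted(Path(series["dir"]).glob("*.dcm"))
        report = ws.import_files(files, "DUPTEST", series["subject"])
        assert report.imported == series["take"]
        ws.assign_nicknames(series["subject"])
    return ws, manifest


@pytest.fixture()
def clean_series(tmp_path):
    """Factory: write one clean synthetic series, returning its paths."""

    def make(n=6, subject="P1", series_number=1, seed=7, **kw):
        spec = fx.SeriesSpec(
            n_images=n,
            patient_id=subject,
            series_number=series_number,
            **kw,
        )
        return fx.generate_series(
            spec, seed, tmp_path / f"{subject}_{series_number}"
        )

    return make


@pytest.fixture()
def workspace(tmp_path):
    return Workspace(tmp_path / "ws")
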