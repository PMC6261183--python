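"""Hunt a twice-duplicated series and reconstruct its proto series.

One original ("proto") series of 206 CT slices at z-offsets -205..0 mm was
submitted three times under different subjects as overlapping, renumbered
series of 195, 187 and 199 files.  Pixel digests expose the duplication;
offset alignment reconstructs the original.
"""

import tempfile
from pathlib import Path

from dicom_curator import duplicates as dup
from dicom_curator import fixtures as fx
from dicom_curator.db import Workspace

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    manifest = fx.build_fig8_fixture(seed=1, out_dir=tmp / "data")
    ws = Workspace(tmp / "ws")
    for series in manifest["series"]:
        files = sorted(Path(series["dir"]).glob("*.dcm"))
        ws.import_files(files, "DUPTEST", series["subject"])

    hist = ws.digest_histogram()
    print("digest histogram:", dict(sorted(hist.items())))
    # {1: 17, 2: 3, 3: 186}: 186 images occur three times — a series
    # duplicated twice.

    (cand,) = dup.find_candidate_duplicate_series(ws, multiplicity=3)
    print(f"candidate: {len(cand.series)} series share {cand.digest_count} digests")

    a, b = cand.series[0], cand.series[1]
    cmp = dup.compare_series(ws, a, b)
    print(f"pairwise: shared={cmp.shared_digest_count}, "
          f"shift={cmp.offset_shift} mm, consistent={cmp.shift_consistent}")

    proto = dup.infer_proto_series(ws, list(cand.series))
    offsets = [im.offset for im in proto.images]
    print(f"proto series: {len(proto.images)} images, "
          f"offsets {offsets[0]}..{offsets[-1]} mm")
    print("anchor (unrenumbered) series:", proto.anchor_series)
    # 206 images spanning -205..0; the third submission kept the original
    # numbering, so it anchors the frame.
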