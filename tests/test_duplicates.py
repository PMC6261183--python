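"""Duplicate digest analysis, series comparison and proto-series inference."""

from collections import defaultdict

import pytest

from dicom_curator import DisconnectedSet, InconsistentShift
from dicom_curator import duplicates as dup
from dicom_curator import fixtures as fx
from dicom_curator.model import parse_bytes


def _series_uid(manifest, label):
    return next(s["series_uid"] for s in manifest["series"] if s["label"] == label)


# -- digest groups ----------------------------------------------------------


def test_all_unique_collection_has_no_groups(workspace, clean_series):
    workspace.import_files(clean_series(n=8), "C", "P1")
    assert dup.find_duplicate_digest_groups(workspace, 2) == []


def test_worked_example_group_counts(fig8):
    ws, _ = fig8
    assert len(dup.find_duplicate_digest_groups(ws, min_count=3)) == 186
    groups2 = dup.find_duplicate_digest_groups(ws, min_count=2)
    assert len(groups2) == 189  # 186 triplets + 3 pairs
    by_count = defaultdict(int)
    for g in groups2:
        by_count[g.file_count] += 1
    assert by_count == {3: 186, 2: 3}


def test_duplicating_a_series_pairs_every_file(workspace, tmp_path):
    # duplicating any series yields one duplicate pair per file in it
    n = 7
    for k in range(2):
        spec = fx.SeriesSpec(
            n_images=n,
            series_number=k + 1,
            patient_id=f"S{k}",
            pixel_indices=list(range(n)),
        )
        paths = fx.generate_series(spec, seed=5, out_dir=tmp_path / str(k))
        workspace.import_files(paths, "C", f"S{k}")
    groups = dup.find_duplicate_digest_groups(workspace, 2)
    assert len(groups) == n
    assert all(g.file_count == 2 for g in groups)


def test_digest_groups_equal_brute_force_pixel_comparison(fig8):
    """Digest grouping must coincide with grouping by raw pixel payload
    bytes (581-file fixture)."""
    ws, _ = fig8
    by_payload = defaultdict(set)
    by_digest = defaultdict(set)
    for row in ws.scope_file_rows():
        pds = parse_bytes(ws.read_object(row["file_digest"]))
        elem = pds.dataset.get_item(dup.PIXEL_DATA_TAG)
        payload = bytes(elem.value)
        by_payload[payload].add((row["subject"], row["nickname"]))
        by_digest[row["pixel_digest"]].add((row["subject"], row["nickname"]))
    assert sorted(map(sorted, by_payload.values())) == sorted(
        map(sorted, by_digest.values())
    )


# -- distinguished digests --------------------------------------------------


def test_blank_images_classified(workspace, tmp_path):
    fx_paths = fx.generate_blank_series(
        n=60,
        byte_value=0,
        sizes=[(64, 64)],
        out_dir=tmp_path / "blank",
        subjects=[f"B{i}" for i in range(12)],
    )
    per_subject = defaultdict(list)
    for i, p in enumerate(fx_paths):
        # generation assigns subjects round-robin in file order
        per_subject[i % 12].append(p)
    for idx, paths in per_subject.items():
        workspace.import_files(paths, "C", f"B{idx}")
    (group,) = dup.find_duplicate_digest_groups(workspace, 2, classify=False)
    assert group.file_count == 60 and len(group.subjects) == 12
    assert dup.classify_distinguished(workspace, group) == "blank"


def test_blank_sizes_make_distinct_digests(workspace, tmp_path):
    fx.generate_blank_series(
        n=5, sizes=[(64, 64), (128, 128)], out_dir=tmp_path / "b"
    )
    paths = sorted((tmp_path / "b").glob("*.dcm"))
    workspace.import_files(paths, "C", "B1")
    groups = dup.find_duplicate_digest_groups(workspace, 2, classify=False)
    assert sorted(g.file_count for g in groups) == [5, 5]
    assert len({g.pixel_digest for g in groups}) == 2


def test_small_triplet_groups_not_distinguished(fig8):
    ws, _ = fig8
    groups = dup.find_duplicate_digest_groups(ws, min_count=3)
    assert all(g.distinguished is None for g in groups)


def test_blocklisted_digest_is_manual(workspace, clean_series):
    paths = clean_series(n=2)
    workspace.import_files(paths, "C", "P1")
    # force a duplicate by re-importing identical pixels under another subject
    spec = fx.SeriesSpec(n_images=2, patient_id="P2", pixel_indices=[0, 1])
    other = fx.generate_series(spec, seed=7, out_dir=paths[0].parent / "p2")
    workspace.import_files(other, "C", "P2")
    (group, *_) = dup.find_duplicate_digest_groups(workspace, 2, classify=False)
    workspace.blocklist_digest(group.pixel_digest, "known phantom")
    assert dup.classify_distinguished(workspace, group) == "manual"


# -- candidate duplicate series --------------------------------------------


def test_candidates_worked_example(fig8):
    ws, manifest = fig8
    cands = dup.find_candidate_duplicate_series(ws, 3)
    assert len(cands) == 1
    assert cands[0].digest_count == 186
    assert set(cands[0].series) == {s["series_uid"] for s in manifest["series"]}


def test_candidates_clean_collection_empty(workspace, clean_series):
    workspace.import_files(clean_series(n=5), "C", "P1")
    assert dup.find_candidate_duplicate_series(workspace, 2) == []


def test_candidates_exact_copy_pair(workspace, tmp_path):
    for k in range(2):
        spec = fx.SeriesSpec(
            n_images=5,
            series_number=k + 1,
            patient_id=f"S{k}",
            pixel_indices=list(range(5)),
        )
        workspace.import_files(
            fx.generate_series(spec, seed=9, out_dir=tmp_path / str(k)),
            "C",
            f"S{k}",
        )
    (cand,) = dup.find_candidate_duplicate_series(workspace, 2)
    assert len(cand.series) == 2 and cand.digest_count == 5


# -- series comparison ------------------------------------------------------


def test_compare_worked_example_series_1_vs_3(fig8):
    ws, manifest = fig8
    cmp = dup.compare_series(
        ws, _series_uid(manifest, "S1"), _series_uid(manifest, "S3")
    )
    # S1 holds proto images 0..194, S3 holds 7..205: 188 shared; S3's local
    # offsets are 11 mm below S1's renumbered ones
    assert cmp.shared_digest_count == 188
    assert cmp.a_only == 7 and cmp.b_only == 11
    assert cmp.shift_consistent and cmp.offset_shift == pytest.approx(-11.0)
    assert cmp.shared_digest_count + cmp.a_only == cmp.a_total
    assert cmp.shared_digest_count + cmp.b_only == cmp.b_total


def test_compare_identical_copies(workspace, tmp_path):
    for k in range(2):
        spec = fx.SeriesSpec(
            n_images=4,
            series_number=k + 1,
            patient_id=f"S{k}",
            pixel_indices=list(range(4)),
            z_start=-3.0,
        )
        workspace.import_files(
            fx.generate_series(spec, seed=13, out_dir=tmp_path / str(k)),
            "C",
            f"S{k}",
        )
    uids = sorted({r["series_uid"] for r in workspace.scope_file_rows()})
    cmp = dup.compare_series(workspace, uids[0], uids[1])
    assert cmp.shared_digest_count == 4
    assert cmp.offset_shift == 0.0 and cmp.shift_consistent


def test_compare_unrelated_series(workspace, clean_series, tmp_path):
    workspace.import_files(clean_series(n=3, subject="A"), "C", "A")
    spec = fx.SeriesSpec(n_images=3, patient_id="B", pixel_seed=99)
    other = fx.generate_series(spec, seed=99, out_dir=tmp_path / "unrelated")
    workspace.import_files(other, "C", "B")
    uids = sorted({r["series_uid"] for r in workspace.scope_file_rows()})
    cmp = dup.compare_series(workspace, uids[0], uids[1])
    assert cmp.shared_digest_count == 0
    assert cmp.offset_shift is None and not cmp.shift_consistent


# -- proto inference --------------------------------------------------------


def test_proto_worked_example(fig8):
    ws, manifest = fig8
    uids = [s["series_uid"] for s in manifest["series"]]
    proto = dup.infer_proto_series(ws, uids)
    assert len(proto.images) == 206
    offsets = [im.offset for im in proto.images]
    assert offsets[0] == -205.0 and offsets[-1] == 0.0
    assert all(b > a for a, b in zip(offsets, offsets[1:]))  # strictly monotone
    assert proto.anchor_series == _series_uid(manifest, "S3")
    assert proto.non_contiguous_series == []
    # exact ground-truth recovery from the manifest
    truth = [(p["pixel_digest"], p["offset"]) for p in manifest["proto"]]
    assert [(im.pixel_digest, im.offset) for im in proto.images] == truth
    # conservation: distinct + overcounts == total files
    total = sum(s["take"] for s in manifest["series"])
    overcount = sum(len(im.membership) - 1 for im in proto.images)
    assert len(proto.images) + overcount == total == 581


def test_single_series_proto_is_identity(workspace, clean_series):
    workspace.import_files(clean_series(n=5), "C", "P1")
    uid = workspace.head_file_rows("P1")[0]["series_uid"]
    proto = dup.infer_proto_series(workspace, [uid])
    assert len(proto.images) == 5 and proto.anchor_series == uid


def test_permuted_offsets_raise_inconsistent_shift():
    records = [
        ("A", [(f"d{k}", float(k)) for k in range(10)]),
        ("B", [(f"d{k}", float(9 - k)) for k in range(10)]),  # permuted
    ]
    with pytest.raises(InconsistentShift):
        dup.infer_proto_from_records(records)


def test_disconnected_series_set_raises():
    records = [
        ("A", [(f"a{k}", float(k)) for k in range(5)]),
        ("B", [(f"b{k}", float(k)) for k in range(5)]),  # zero shared images
    ]
    with pytest.raises(DisconnectedSet):
        dup.infer_proto_from_records(records)


def _records_from_manifest(manifest):
    return [
        (
            s["series_uid"],
            [(f["pixel_digest"], f["local_offset"]) for f in s["files"]],
        )
        for s in manifest["series"]
    ]


@pytest.mark.parametrize("seed", range(50))
def test_parameter_recovery_randomized_overlaps(seed):
    """Inferred proto digest order and offsets equal the generator's ground
    truth for randomized overlapping-series layouts (proto 20-300 images)."""
    proto_n, slices = fx.random_overlap_spec(seed)
    manifest = fx.overlap_manifest(proto_n, slices, seed)
    proto = dup.infer_proto_from_records(_records_from_manifest(manifest))
    truth = [(p["pixel_digest"], p["offset"]) for p in manifest["proto"]]
    # slices need not cover the whole proto: truth restricted to images present
    present = {
        f["pixel_digest"] for s in manifest["series"] for f in s["files"]
    }
    truth = [t for t in truth if t[0] in present]
    assert [(im.pixel_digest, im.offset) for im in proto.images] == truth
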