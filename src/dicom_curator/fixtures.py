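"""Synthetic DICOM generators for exercising the curation workflow.

Everything here is deterministic: the same spec and seed produce
byte-identical Part 10 files.  The generators emulate desk-scale CT-like
collections — multi-series subjects, planted entity-attribute
inconsistencies, blank images of various sizes, and the overlapping
duplicated-series structure used for proto-series inference:

* a *proto* series of ``n`` images at z-offsets ``-(n-1)..0`` mm, unique
  pixel content per image;
* submitted series that each take a contiguous run of the proto images and
  renumber their offsets to end at 0 (the run that reaches the proto's last
  image keeps its offsets unchanged).

The worked three-series example builds Series 1 = first 195 images
(renumbered from −194), Series 2 = skip 9 / take 187 (from −186) and
Series 3 = skip 7 / take 199 (offsets −198..0, no renumbering needed), for
581 files over a 206-image proto.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .model import Tag, mutate_element, parse_file

#: reserved test root; never collides with real-world UIDs
UID_ROOT = "1.2.826.0.1.3680043.8.498.77"

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

#: sentinel for an "element deleted" bucket in inconsistency plans
ABSENT = object()


def test_uid(seed: int, *parts: int) -> str:
    tail = ".".join(str(p) for p in (seed,) + parts)
    return f"{UID_ROOT}.{tail}"


def pixel_payload(seed: int, index: int, rows: int = 64, cols: int = 64) -> bytes:
    """Unique-per-(seed, index) 16-bit pixel block, stable across calls."""
    rng = np.random.default_rng((seed & 0x7FFFFFFF) * 2_000_003 + index)
    return rng.integers(0, 4096, size=(rows, cols), dtype=np.uint16).tobytes()


def pixel_digest_of(seed: int, index: int, rows: int = 64, cols: int = 64) -> str:
    return hashlib.md5(pixel_payload(seed, index, rows, cols)).hexdigest()


@dataclass
class SeriesSpec:
    """Recipe for one synthetic series.

    ``pixel_indices`` maps each image to a pixel-content index so the same
    content can appear in several series (proto overlap); by default image
    ``i`` gets index ``i``.
    """

    n_images: int
    modality: str = "CT"
    description: str = "SYNTHETIC"
    z_start: float = 0.0
    z_spacing: float = 1.0
    rows: int = 64
    cols: int = 64
    patient_id: str = "P1"
    patient_name: str = "Synthetic^Subject"
    study_uid: Optional[str] = None
    series_uid: Optional[str] = None
    frame_of_reference_uid: Optional[str] = None
    series_number: int = 1
    instance_start: int = 1
    pixel_seed: Optional[int] = None  # defaults to the generation seed
    pixel_indices: Optional[Sequence[int]] = None
    tag_overrides: dict = field(default_factory=dict)  # "GGGG,EEEE" -> value


def build_dataset(
    spec: SeriesSpec,
    i: int,
    seed: int,
    sop_uid: str,
    payload: Optional[bytes] = None,
    z: Optional[float] = None,
) -> FileDataset:
    """One CT-like image dataset; explicit-VR little-endian, fixed dates."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)

    ds.SOPClassUID = CT_SOP_CLASS
    ds.SOPInstanceUID = sop_uid
    ds.StudyDate = "20180102"
    ds.StudyTime = "120000"
    ds.AccessionNumber = "ACC1"
    ds.Modality = spec.modality
    ds.StudyDescription = "SYNTHETIC STUDY"
    ds.SeriesDescription = spec.description
    ds.PatientName = spec.patient_name
    ds.PatientID = spec.patient_id
    ds.PatientBirthDate = "19700101"
    ds.PatientSex = "O"
    ds.BodyPartExamined = "CHEST"
    ds.StudyInstanceUID = spec.study_uid or test_uid(seed, 1, spec.series_number, 1)
    ds.SeriesInstanceUID = spec.series_uid or test_uid(seed, 2, spec.series_number)
    ds.StudyID = "1"
    ds.SeriesNumber = spec.series_number
    ds.InstanceNumber = spec.instance_start + i
    ds.FrameOfReferenceUID = spec.frame_of_reference_uid or test_uid(
        seed, 3, spec.series_number
    )
    if z is None:
        z = spec.z_start + i * spec.z_spacing
    ds.ImagePositionPatient = ["0.0", "0.0", _fmt_ds(z)]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.SliceLocation = _fmt_ds(z)
    ds.SliceThickness = _fmt_ds(abs(spec.z_spacing) or 1.0)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = spec.rows
    ds.Columns = spec.cols
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.RescaleIntercept = "-1024"
    ds.RescaleSlope = "1"
    if payload is None:
        idx = spec.pixel_indices[i] if spec.pixel_indices is not None else i
        pseed = spec.pixel_seed if spec.pixel_seed is not None else seed
        payload = pixel_payload(pseed, idx, spec.rows, spec.cols)
    ds.PixelData = payload
    for tag_text, value in spec.tag_overrides.items():
        tag = Tag.parse(tag_text)
        setattr_by_tag(ds, tag, value)
    return ds


def setattr_by_tag(ds, tag: Tag, value) -> None:
    from pydicom.datadict import dictionary_VR

    try:
        vr = dictionary_VR(tag.pydicom)
    except KeyError:
        vr = "LO"
    ds.add_new(tag.pydicom, vr, value)


def _fmt_ds(v: float) -> str:
    # decimal-string render without float noise; fixtures use exact values
    s = f"{v:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def dataset_bytes(ds: FileDataset) -> bytes:
    from io import BytesIO

    buf = BytesIO()
    pydicom.dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


def generate_series(
    spec: SeriesSpec, seed: int, out_dir: Union[str, Path]
) -> list[Path]:
    """Write one series to ``out_dir``; returns the file paths in order."""
    if spec.n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(spec.n_images):
        sop_uid = test_uid(seed, 9, spec.series_number, i + 1)
        ds = build_dataset(spec, i, seed, sop_uid)
        path = out / f"{spec.modality}_{spec.series_number:02d}_{i + 1:04d}.dcm"
        path.write_bytes(dataset_bytes(ds))
        paths.append(path)
    return paths


def plant_inconsistency(
    files: Sequence[Union[str, Path]],
    tag: Union[str, Tag],
    plan: Sequence[tuple[object, int]],
) -> list[Path]:
    """Rewrite files so a tag takes bucketed values.

    ``plan`` is a list of ``(value, count)`` pairs consumed in file order
    and must partition the file list; a value of :data:`ABSENT` deletes the
    element in that bucket.  A one-bucket plan plants nothing worth finding.
    """
    tag = tag if isinstance(tag, Tag) else Tag.parse(str(tag))
    if sum(c for _, c in plan) != len(files):
        raise ValueError("bucket plan does not partition the file list")
    it = iter(files)
    touched = []
    for value, count in plan:
        for _ in range(count):
            path = Path(next(it))
            pds = parse_file(path)
            if value is ABSENT:
                pds = mutate_element(pds, f"{tag}", "delete")
            else:
                pds = mutate_element(pds, f"{tag}", "set", value=value)
            path.write_bytes(pds.serialize())
            touched.append(path)
    return touched


def plant_unique_values(
    files: Sequence[Union[str, Path]], tag: Union[str, Tag], prefix: str
) -> list[Path]:
    """Give every file its own value — the per-slice Frame of Reference or
    per-image Series Description pathology."""
    return plant_inconsistency(
        files, tag, [(f"{prefix}{i + 1}", 1) for i in range(len(files))]
    )


# ---------------------------------------------------------------------------
# overlapping duplicated series


@dataclass(frozen=True)
class SeriesSlice:
    """One submitted series as a contiguous slice of the proto series."""

    skip: int
    take: int
    label: str


#: the worked three-series overlap example: 206-image proto, 581 files
WORKED_EXAMPLE_SLICES = (
    SeriesSlice(0, 195, "S1"),
    SeriesSlice(9, 187, "S2"),
    SeriesSlice(7, 199, "S3"),
)
WORKED_EXAMPLE_PROTO_N = 206


def overlap_manifest(
    proto_n: int, slices: Sequence[SeriesSlice], seed: int
) -> dict:
    """Ground truth for an overlap fixture, sufficient to verify every
    downstream inference exactly.

    Proto offsets are ``-(proto_n-1)..0``; a series of length ``take``
    renumbers to ``-(take-1)..0``, which is the identity exactly when the
    series reaches the proto's last image.
    """
    for s in slices:
        if s.skip < 0 or s.take < 1 or s.skip + s.take > proto_n:
            raise ValueError(f"slice {s} does not fit a {proto_n}-image proto")
    proto = [
        {
            "proto_index": k,
            "offset": float(k - (proto_n - 1)),
            "pixel_digest": pixel_digest_of(seed, k),
        }
        for k in range(proto_n)
    ]
    series = []
    for idx, s in enumerate(slices):
        series_uid = test_uid(seed, 2, idx + 1)
        files = []
        for j in range(s.take):
            k = s.skip + j
            files.append(
                {
                    "proto_index": k,
                    "local_offset": float(j - (s.take - 1)),
                    "true_offset": proto[k]["offset"],
                    "pixel_digest": proto[k]["pixel_digest"],
                }
            )
        series.append(
            {
                "label": s.label,
                "series_uid": series_uid,
                "subject": f"SUBJ{idx + 1}",
                "skip": s.skip,
                "take": s.take,
                "files": files,
            }
        )
    return {"seed": seed, "proto_n": proto_n, "proto": proto, "series": series}


def build_overlap_fixture(
    proto_n: int,
    slices: Sequence[SeriesSlice],
    seed: int,
    out_dir: Union[str, Path],
) -> dict:
    """Write an overlap fixture to disk: one directory per submitted series
    (each under its own subject), plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = overlap_manifest(proto_n, slices, seed)
    for idx, series in enumerate(manifest["series"]):
        spec = SeriesSpec(
            n_images=series["take"],
            description=f"DUP {series['label']}",
            patient_id=series["subject"],
            patient_name=f"Subject^{idx + 1}",
            study_uid=test_uid(seed, 1, idx + 1),
            series_uid=series["series_uid"],
            frame_of_reference_uid=test_uid(seed, 3, idx + 1),
            series_number=idx + 1,
            pixel_seed=seed,
            pixel_indices=[f["proto_index"] for f in series["files"]],
            z_start=-(series["take"] - 1),
            z_spacing=1.0,
        )
        sdir = out / series["label"]
        paths = generate_series(spec, seed, sdir)
        for f, p in zip(series["files"], paths):
            f["path"] = str(p)
        series["dir"] = str(sdir)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def build_fig8_fixture(seed: int, out_dir: Union[str, Path]) -> dict:
    """The worked duplicated-series example: three overlapping series
    (195 + 187 + 199 files) cut from a 206-image proto."""
    return build_overlap_fixture(
        WORKED_EXAMPLE_PROTO_N, WORKED_EXAMPLE_SLICES, seed, out_dir
    )


def random_overlap_spec(seed: int) -> tuple[int, list[SeriesSlice]]:
    """Random proto length 20–300 with 2–4 overlapping slices.

    One slice always reaches the proto's tail (the unrenumbered series);
    slices are drawn until the pairwise shared-image graph is connected
    with at least two shared images per edge used.
    """
    rng = np.random.default_rng(seed)
    proto_n = int(rng.integers(20, 301))
    n_series = int(rng.integers(2, 5))
    for _ in range(200):
        slices = []
        skip = int(rng.integers(0, proto_n - 10 + 1))
        slices.append(SeriesSlice(skip, proto_n - skip, "S1"))
        for i in range(1, n_series):
            lo = int(rng.integers(0, proto_n - 10 + 1))
            hi = int(rng.integers(lo + 10, proto_n + 1))
            slices.append(SeriesSlice(lo, hi - lo, f"S{i + 1}"))
        if _connected(slices):
            return proto_n, slices
    raise RuntimeError("could not draw a connected overlap spec")


def _connected(slices: Sequence[SeriesSlice]) -> bool:
    n = len(slices)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = slices[i], slices[j]
            shared = min(a.skip + a.take, b.skip + b.take) - max(a.skip, b.skip)
            if shared >= 2:
                adj[i].add(j)
                adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


# ---------------------------------------------------------------------------
# blank images


def generate_blank_series(
    n: int,
    byte_value: int = 0,
    sizes: Sequence[tuple[int, int]] = ((64, 64),),
    out_dir: Union[str, Path] = ".",
    seed: int = 0,
    subjects: Sequence[str] = ("BLANK1",),
    series_number_start: int = 90,
) -> list[Path]:
    """``n`` constant-fill images per size, spread round-robin over subjects.

    All files of one size share a single pixel digest; different sizes
    differ (the payload length differs).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    counter = 0
    for s_idx, (rows, cols) in enumerate(sizes):
        payload = bytes([byte_value & 0xFF]) * (rows * cols * 2)
        for i in range(n):
            subject = subjects[counter % len(subjects)]
            series_number = series_number_start + s_idx * len(subjects) + (
                counter % len(subjects)
            )
            spec = SeriesSpec(
                n_images=1,
                description=f"BLANK {rows}x{cols}",
                patient_id=subject,
                rows=rows,
                cols=cols,
                series_number=series_number,
                pixel_seed=seed,
            )
            sop_uid = test_uid(seed, 8, s_idx + 1, counter + 1)
            ds = build_dataset(spec, i, seed, sop_uid, payload=payload, z=float(i))
            ds.InstanceNumber = i + 1
            path = out / f"BLANK_{rows}x{cols}_{counter + 1:04d}.dcm"
            path.write_bytes(dataset_bytes(ds))
            paths.append(path)
            counter += 1
    return paths
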