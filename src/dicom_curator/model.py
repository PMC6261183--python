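"""Permissive DICOM parsing, pixel digesting and element-level mutation.

The model stores DICOM "as it is": any stream that can be framed into
elements is accepted, and conformance problems (missing required
attributes, suspect values, broken entity hierarchies) become parse *notes*
rather than exceptions.  The only rejection path is a stream that is
truncated or garbled beyond element framing.

Pixel identity is a cryptographic digest (MD5 by default) over the stored
value bytes of the pixel-data element, exactly as encoded in the file.  For
encapsulated transfer syntaxes the digest covers the concatenated fragment
payloads, excluding item headers and the basic offset table.  Two files
share a digest iff their stored pixel payloads are byte-identical; hash
collisions are treated as impossible at curation scale.
"""

from __future__ import annotations

import copy
import hashlib
import re
import struct
import warnings
from dataclasses import dataclass, field, replace
from io import BytesIO
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pydicom
import pydicom.config
from pydicom.datadict import dictionary_VR
from pydicom.dataelem import DataElement, RawDataElement
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.multival import MultiValue
from pydicom.tag import Tag as _PTag
from pydicom.uid import UID, ExplicitVRLittleEndian, ImplicitVRLittleEndian

from .errors import BadPath, SequenceIndexOutOfRange, UnparseableStream

# keep pydicom from raising over nonconformant values; problems surface as
# warnings which parse_bytes records as notes
pydicom.config.settings.reading_validation_mode = pydicom.config.WARN
pydicom.config.settings.writing_validation_mode = pydicom.config.WARN

NO_PIXELS = "NO_PIXELS"
PIXEL_DATA_TAG = _PTag(0x7FE0, 0x0010)

_TAG_RE = re.compile(r"^([0-9A-Fa-f]{4}),([0-9A-Fa-f]{4})$")
_SEG_RE = re.compile(r"^([0-9A-Fa-f]{4}),([0-9A-Fa-f]{4})(?:\[(\d+)\])?$")

#: entity-level attributes extracted for every file
ENTITY_TAGS = {
    "patient_id": (0x0010, 0x0020),
    "study_uid": (0x0020, 0x000D),
    "series_uid": (0x0020, 0x000E),
    "sop_uid": (0x0008, 0x0018),
    "sop_class": (0x0008, 0x0016),
    "frame_of_reference_uid": (0x0020, 0x0052),
}


@dataclass(frozen=True, order=True)
class Tag:
    """A DICOM (group, element) tag, rendered canonically as ``GGGG,EEEE``."""

    group: int
    element: int

    def __post_init__(self) -> None:
        for v in (self.group, self.element):
            if not 0 <= v <= 0xFFFF:
                raise BadPath(f"tag component out of range: {v:#x}")

    def render(self) -> str:
        return f"{self.group:04X},{self.element:04X}"

    __str__ = render

    @classmethod
    def parse(cls, text: str) -> "Tag":
        m = _TAG_RE.match(text.strip())
        if not m:
            raise BadPath(f"not a GGGG,EEEE tag: {text!r}")
        return cls(int(m.group(1), 16), int(m.group(2), 16))

    @property
    def pydicom(self) -> _PTag:
        return _PTag(self.group, self.element)


@dataclass(frozen=True)
class PathSegment:
    tag: Tag
    item: Optional[int] = None  # 0-based sequence item index


@dataclass(frozen=True)
class ElementPath:
    """Address of one element occurrence, possibly nested in sequence items.

    Every non-final segment descends into a sequence and therefore carries
    an item index; the final segment never does.  Renders as e.g.
    ``3006,0010[0]/0020,0052``.
    """

    segments: tuple[PathSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise BadPath("empty element path")
        for seg in self.segments[:-1]:
            if seg.item is None:
                raise BadPath(
                    f"non-final path segment {seg.tag} lacks an item index"
                )
            if seg.item < 0:
                raise BadPath(f"negative item index in {seg.tag}")
        if self.segments[-1].item is not None:
            raise BadPath("final path segment must not carry an item index")

    def render(self) -> str:
        parts = []
        for seg in self.segments:
            s = seg.tag.render()
            if seg.item is not None:
                s += f"[{seg.item}]"
            parts.append(s)
        return "/".join(parts)

    __str__ = render

    @classmethod
    def parse(cls, text: Union[str, "ElementPath", Tag]) -> "ElementPath":
        if isinstance(text, ElementPath):
            return text
        if isinstance(text, Tag):
            return cls((PathSegment(text),))
        segs = []
        for part in str(text).split("/"):
            m = _SEG_RE.match(part.strip())
            if not m:
                raise BadPath(f"malformed path segment: {part!r}")
            tag = Tag(int(m.group(1), 16), int(m.group(2), 16))
            item = int(m.group(3)) if m.group(3) is not None else None
            segs.append(PathSegment(tag, item))
        return cls(tuple(segs))

    @classmethod
    def top_level(cls, tag: Tag) -> "ElementPath":
        return cls((PathSegment(tag),))


@dataclass(frozen=True)
class PixelDigest:
    """Hex digest of the stored pixel payload, or the ``NO_PIXELS`` sentinel."""

    hex: str

    @property
    def is_no_pixels(self) -> bool:
        return self.hex == NO_PIXELS

    def __str__(self) -> str:
        return self.hex


@dataclass(frozen=True)
class EntityKeys:
    """The six entity-identifying attributes; ``None`` means absent.

    An empty string is a real (present, empty) value and is deliberately
    distinct from absence — consistency reports treat them as different
    buckets.
    """

    patient_id: Optional[str] = None
    study_uid: Optional[str] = None
    series_uid: Optional[str] = None
    sop_uid: Optional[str] = None
    sop_class: Optional[str] = None
    frame_of_reference_uid: Optional[str] = None


@dataclass
class ParsedDataset:
    """One DICOM file held exactly as encoded.

    Wraps a pydicom dataset whose untouched elements stay *raw* (undecoded
    bytes), so re-serialization is byte-faithful.  ``source_bytes`` holds
    the original stream and is dropped on the first mutation.
    """

    dataset: Dataset
    transfer_syntax: str
    source_bytes: Optional[bytes] = None
    parse_notes: list[str] = field(default_factory=list)
    source_path: Optional[str] = None

    # -- serialization ----------------------------------------------------

    def serialize(self) -> bytes:
        """Encode back to a Part 10 stream.

        Unmutated datasets return the original bytes verbatim.  Mutated
        datasets are re-encoded; untouched elements are written from their
        raw bytes and remain byte-identical for explicit-VR little-endian
        inputs.  Implicit-VR or big-endian inputs are converted to
        explicit-VR little-endian on write.
        """
        if self.source_bytes is not None:
            return self.source_bytes
        ds = self.dataset
        _ensure_file_meta(ds)
        buf = BytesIO()
        pydicom.dcmwrite(buf, ds, enforce_file_format=True)
        return buf.getvalue()

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_bytes(self.serialize())


# ---------------------------------------------------------------------------
# parsing


def parse_bytes(data: bytes, origin: str = "<bytes>") -> ParsedDataset:
    """Parse a DICOM stream permissively; only framing failures reject."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            ds = pydicom.dcmread(BytesIO(data), force=True)
        except Exception as exc:  # noqa: BLE001 - any framing failure rejects
            raise UnparseableStream(f"{origin}: {exc}") from None
    _check_framing(ds, data, origin)
    notes = sorted({str(w.message) for w in caught})
    return ParsedDataset(
        dataset=ds,
        transfer_syntax=_transfer_syntax_of(ds),
        source_bytes=data,
        parse_notes=notes,
        source_path=None,
    )


def parse_file(path: Union[str, Path]) -> ParsedDataset:
    """Parse one file from disk; see :func:`parse_bytes`."""
    p = Path(path)
    pds = parse_bytes(p.read_bytes(), origin=str(p))
    pds.source_path = str(p)
    return pds


def _check_framing(ds: Dataset, data: bytes, origin: str) -> None:
    # a stream counts as DICOM if it carries the DICM magic or at least one
    # element whose tag the standard dictionary knows
    has_magic = len(data) >= 132 and data[128:132] == b"DICM"
    meaningful = has_magic
    for tag in ds.keys():
        if not meaningful and tag.group >= 0x0008:
            # group 0000/0002 "elements" also appear when force-reading zero
            # padding, so only standard data elements count as evidence
            try:
                dictionary_VR(tag)
                meaningful = True
            except KeyError:
                pass
        raw = ds.get_item(tag)
        declared = getattr(raw, "length", None)
        value = getattr(raw, "value", None)
        if (
            declared is not None
            and declared != 0xFFFFFFFF
            and isinstance(value, (bytes, bytearray))
            and len(value) != declared
        ):
            raise UnparseableStream(
                f"{origin}: element {tag} truncated "
                f"({len(value)} of {declared} bytes)"
            )
    if len(ds) == 0 or not meaningful:
        raise UnparseableStream(f"{origin}: no recognizable DICOM elements")


def _transfer_syntax_of(ds: Dataset) -> str:
    meta = getattr(ds, "file_meta", None)
    if meta is not None and "TransferSyntaxUID" in meta:
        return str(meta.TransferSyntaxUID)
    implicit, little = ds.original_encoding
    if implicit:
        return "1.2.840.10008.1.2"
    return "1.2.840.10008.1.2.1" if little else "1.2.840.10008.1.2.2"


def _ensure_file_meta(ds: Dataset) -> None:
    meta = getattr(ds, "file_meta", None)
    if meta is None:
        meta = FileMetaDataset()
        ds.file_meta = meta
    ts = meta.get("TransferSyntaxUID")
    if ts is None or UID(str(ts)).is_implicit_VR or not UID(str(ts)).is_little_endian:
        # serialization targets explicit-VR little-endian
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
    if "MediaStorageSOPClassUID" not in meta and "SOPClassUID" in ds:
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
    if "MediaStorageSOPInstanceUID" not in meta and "SOPInstanceUID" in ds:
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID


# ---------------------------------------------------------------------------
# digests


def compute_pixel_digest(pds: ParsedDataset, algorithm: str = "md5") -> PixelDigest:
    """Digest the stored pixel payload; ``NO_PIXELS`` if the element is absent."""
    ds = pds.dataset
    if PIXEL_DATA_TAG not in ds:
        return PixelDigest(NO_PIXELS)
    elem = ds.get_item(PIXEL_DATA_TAG)
    value = elem.value
    if value is None:
        payload = b""
    elif isinstance(value, (bytes, bytearray)):
        payload = bytes(value)
    else:  # pixel data held as a buffered/converted object
        payload = bytes(value)
    if UID(pds.transfer_syntax).is_encapsulated:
        payload = _defragment(payload)
    return PixelDigest(hashlib.new(algorithm, payload).hexdigest())


def _defragment(encapsulated: bytes) -> bytes:
    """Concatenate fragment payloads, dropping item headers and the basic
    offset table (always the first item)."""
    out = []
    pos = 0
    first = True
    n = len(encapsulated)
    while pos + 8 <= n:
        group, element, length = struct.unpack_from("<HHI", encapsulated, pos)
        pos += 8
        if (group, element) == (0xFFFE, 0xE0DD):  # sequence delimiter
            break
        if (group, element) != (0xFFFE, 0xE000):
            raise UnparseableStream(
                f"bad encapsulated item tag ({group:04x},{element:04x})"
            )
        chunk = encapsulated[pos : pos + length]
        pos += length
        if first:
            first = False  # basic offset table — excluded
            continue
        out.append(chunk)
    return b"".join(out)


def compute_file_digest(data: bytes, algorithm: str = "md5") -> str:
    return hashlib.new(algorithm, data).hexdigest()


# ---------------------------------------------------------------------------
# entity keys


def extract_entity_keys(pds: ParsedDataset) -> EntityKeys:
    """Read the six entity attributes; absent stays ``None``, empty stays ``""``."""
    values = {}
    for name, (g, e) in ENTITY_TAGS.items():
        values[name] = top_level_text(pds.dataset, Tag(g, e))
    return EntityKeys(**values)


def top_level_text(ds: Dataset, tag: Tag) -> Optional[str]:
    """Best-effort text of a top-level element; ``None`` if absent."""
    ptag = tag.pydicom
    if ptag not in ds:
        return None
    raw = ds.get_item(ptag)
    value = getattr(raw, "value", None)
    if isinstance(raw, RawDataElement):
        b = bytes(value or b"")
        return _strip_pad_text(b.decode("ascii", "replace"))
    if value is None:
        return ""
    if isinstance(value, (bytes, bytearray)):
        return _strip_pad_text(bytes(value).decode("ascii", "replace"))
    if isinstance(value, (MultiValue, list, tuple)):
        return "\\".join(str(v) for v in value)
    return str(value)


def _strip_pad_text(s: str) -> str:
    # DICOM pads to even length with a single trailing space or NUL
    if s and s[-1] in ("\x00", " "):
        return s[:-1]
    return s


def strip_pad(b: bytes) -> bytes:
    """Strip at most one trailing DICOM pad byte (space or NUL)."""
    if b and b[-1] in (0x00, 0x20):
        return b[:-1]
    return b


# ---------------------------------------------------------------------------
# element walking (shared by the intake DB and revision diffs)

_NUMERIC_PACK = {
    "US": "<H",
    "SS": "<h",
    "UL": "<I",
    "SL": "<i",
    "FL": "<f",
    "FD": "<d",
}


@dataclass(frozen=True)
class ElementRow:
    path: str
    vr: str
    value: Optional[bytes]  # None for pixel data / sequence containers
    value_text: str


def iter_element_rows(pds: ParsedDataset) -> Iterator[ElementRow]:
    """Walk every element occurrence in encoded tag order, depth first.

    Pixel data contributes a row without value bytes (the digest lives on
    the file record); sequences contribute a container row plus rows for
    every nested element with an ``[item]``-indexed path.
    """
    yield from _walk(pds.dataset, "")


def _walk(ds: Dataset, prefix: str) -> Iterator[ElementRow]:
    for ptag in sorted(ds.keys()):
        tag = Tag(ptag.group, ptag.element)
        path = f"{prefix}{tag.render()}"
        raw = ds.get_item(ptag)
        vr = getattr(raw, "VR", None) or _lookup_vr(ptag)
        if ptag == PIXEL_DATA_TAG:
            size = getattr(raw, "length", None)
            yield ElementRow(path, vr or "OW", None, f"<pixel data, {size} bytes>")
            continue
        if vr == "SQ" or _is_sequence(ds, ptag, raw):
            elem = ds[ptag]  # converts; parses the items
            items = elem.value or []
            yield ElementRow(path, "SQ", None, f"<sequence, {len(items)} items>")
            for i, item in enumerate(items):
                yield from _walk(item, f"{path}[{i}]/")
            continue
        vb = element_value_bytes(raw, vr)
        yield ElementRow(path, vr or "UN", vb, _text_of(vb, vr))


def _lookup_vr(ptag: _PTag) -> str:
    try:
        return dictionary_VR(ptag)
    except KeyError:
        return "UN"


def _is_sequence(ds: Dataset, ptag: _PTag, raw) -> bool:
    if getattr(raw, "VR", None) == "SQ":
        return True
    if isinstance(raw, RawDataElement) and raw.VR is None:
        return _lookup_vr(ptag) == "SQ"
    from pydicom.sequence import Sequence as _Seq

    return isinstance(getattr(raw, "value", None), _Seq)


def element_value_bytes(elem, vr: Optional[str]) -> bytes:
    """Encoded value bytes of an element, re-packing converted values so raw
    and converted forms of the same value compare equal."""
    value = getattr(elem, "value", None)
    if isinstance(elem, RawDataElement):
        return bytes(value or b"")
    if value is None:
        return b""
    if isinstance(value, (bytes, bytearray)):
        return bytes(value)
    vals = list(value) if isinstance(value, (MultiValue, list, tuple)) else [value]
    if vr in _NUMERIC_PACK:
        return b"".join(struct.pack(_NUMERIC_PACK[vr], v) for v in vals)
    if vr == "AT":
        return b"".join(
            struct.pack("<HH", _PTag(v).group, _PTag(v).element) for v in vals
        )
    s = "\\".join(str(v) for v in vals)
    b = s.encode("utf-8", "replace")
    if len(b) % 2:
        b += b"\x00" if vr in ("UI",) else b" "
    return b


def _text_of(vb: bytes, vr: Optional[str]) -> str:
    if vr in _NUMERIC_PACK and vb:
        fmt = _NUMERIC_PACK[vr]
        width = struct.calcsize(fmt)
        if len(vb) % width == 0:
            return "\\".join(
                str(struct.unpack_from(fmt, vb, o)[0])
                for o in range(0, len(vb), width)
            )
    return _strip_pad_text(vb.decode("ascii", "replace"))


# ---------------------------------------------------------------------------
# mutation


def mutate_element(
    pds: ParsedDataset,
    path: Union[str, ElementPath],
    action: str,
    value=None,
    vr: Optional[str] = None,
) -> ParsedDataset:
    """Return a new dataset with one element set or deleted.

    ``set`` preserves the existing VR unless one is supplied (dictionary
    lookup for brand-new elements); insertion keeps tag order.  ``delete``
    of an absent element is a no-op.  The input dataset is never modified.
    """
    epath = ElementPath.parse(path)
    if action not in ("set", "delete"):
        raise ValueError(f"unknown action {action!r}")
    new_ds = copy.deepcopy(pds.dataset)
    container = new_ds
    for seg in epath.segments[:-1]:
        ptag = seg.tag.pydicom
        if ptag not in container:
            raise BadPath(f"{seg.tag} absent while descending {epath}")
        elem = container[ptag]
        if elem.VR != "SQ":
            raise BadPath(f"{seg.tag} is not a sequence (VR {elem.VR})")
        items = elem.value or []
        if seg.item >= len(items):
            raise SequenceIndexOutOfRange(
                f"{seg.tag}[{seg.item}] beyond {len(items)} items"
            )
        container = items[seg.item]
    last = epath.segments[-1].tag
    ptag = last.pydicom
    if action == "delete":
        if ptag in container:
            del container[ptag]
    else:
        if vr is None:
            if ptag in container:
                existing = container.get_item(ptag)
                vr = getattr(existing, "VR", None) or _lookup_vr(ptag)
            else:
                vr = _lookup_vr(ptag)
        container[ptag] = DataElement(ptag, vr, _coerce_value(vr, value))
    return ParsedDataset(
        dataset=new_ds,
        transfer_syntax=pds.transfer_syntax,
        source_bytes=None,  # dirty: must re-serialize
        parse_notes=list(pds.parse_notes),
        source_path=pds.source_path,
    )


def _coerce_value(vr: str, value):
    if value is None:
        return None
    if vr in ("OB", "OW", "OD", "OF", "OL", "OV", "UN"):
        if isinstance(value, str):
            return value.encode("ascii")
        return bytes(value)
    if isinstance(value, (bytes, bytearray)):
        text = bytes(value).decode("ascii", "replace")
        text = _strip_pad_text(text)
        value = text
    if vr in _NUMERIC_PACK and isinstance(value, str):
        num = float(value)
        return int(num) if vr not in ("FL", "FD") else num
    if vr in ("IS",) and isinstance(value, str) and value:
        return value
    return value
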