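"""Minimal DICOM reader/writer (explicit VR, little endian, uncompressed).

Covers exactly the subset the pipeline needs: RT Dose grids and RT Structure
Set planar contours.  Sequences (defined or undefined length) are supported;
compressed transfer syntaxes, implicit VR and big-endian files are rejected
with a :class:`~dosiomics.core.FormatError`.

A dataset is represented as ``dict[(group, element)] -> value`` where numeric
string VRs (DS/IS) decode to floats/ints (a list when multi-valued), text VRs
decode to ``str``, binary VRs stay ``bytes`` and SQ decodes to a list of
nested dataset dicts.
"""

from __future__ import annotations

import struct
from typing import Any

from .core import FormatError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# VRs with a 2-byte reserved field and 4-byte length in explicit encoding
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}

_TEXT_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UI", "UT", "UC", "UR"}

_BINARY_FMT = {"US": "<H", "SS": "<h", "UL": "<I", "SL": "<i", "FL": "<f", "FD": "<d"}

ITEM_TAG = (0xFFFE, 0xE000)
ITEM_DELIM_TAG = (0xFFFE, 0xE00D)
SEQ_DELIM_TAG = (0xFFFE, 0xE0DD)
UNDEFINED_LENGTH = 0xFFFFFFFF


def _decode(vr: str, raw: bytes) -> Any:
    if vr in _BINARY_FMT:
        fmt = _BINARY_FMT[vr]
        size = struct.calcsize(fmt)
        n = len(raw) // size
        vals = [struct.unpack_from(fmt, raw, i * size)[0] for i in range(n)]
        return vals[0] if n == 1 else vals
    if vr == "DS":
        parts = [p for p in raw.decode("ascii").split("\\") if p.strip()]
        vals = [float(p) for p in parts]
        return vals[0] if len(vals) == 1 else vals
    if vr == "IS":
        parts = [p for p in raw.decode("ascii").split("\\") if p.strip()]
        vals = [int(p) for p in parts]
        return vals[0] if len(vals) == 1 else vals
    if vr in _TEXT_VRS:
        text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
        if "\\" in text:
            return text.split("\\")
        return text
    return raw  # OB/OW/UN: caller interprets


class _Reader:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def eof(self) -> bool:
        return self.pos >= len(self.data)

    def _tag(self) -> tuple[int, int]:
        g, e = struct.unpack_from("<HH", self.data, self.pos)
        self.pos += 4
        return g, e

    def read_element(self) -> tuple[tuple[int, int], str, Any]:
        tag = self._tag()
        if tag[0] == 0xFFFE:  # delimitation items carry no VR
            (length,) = struct.unpack_from("<I", self.data, self.pos)
            self.pos += 4
            return tag, "", length
        vr = self.data[self.pos : self.pos + 2].decode("ascii")
        self.pos += 2
        if vr in _LONG_VRS:
            self.pos += 2  # reserved
            (length,) = struct.unpack_from("<I", self.data, self.pos)
            self.pos += 4
        else:
            (length,) = struct.unpack_from("<H", self.data, self.pos)
            self.pos += 2
        if vr == "SQ":
            return tag, vr, self._read_sequence(length)
        if length == UNDEFINED_LENGTH:
            raise FormatError(f"undefined length outside SQ at tag {tag}")
        raw = self.data[self.pos : self.pos + length]
        self.pos += length
        return tag, vr, _decode(vr, raw)

    def _read_sequence(self, length: int) -> list[dict]:
        items: list[dict] = []
        end = None if length == UNDEFINED_LENGTH else self.pos + length
        while True:
            if end is not None and self.pos >= end:
                break
            tag = self._tag()
            (item_len,) = struct.unpack_from("<I", self.data, self.pos)
            self.pos += 4
            if tag == SEQ_DELIM_TAG:
                break
            if tag != ITEM_TAG:
                raise FormatError(f"expected sequence item, got tag {tag}")
            items.append(self._read_item(item_len))
        return items

    def _read_item(self, length: int) -> dict:
        ds: dict = {}
        end = None if length == UNDEFINED_LENGTH else self.pos + length
        while True:
            if end is not None and self.pos >= end:
                break
            save = self.pos
            tag = self._tag()
            if tag == ITEM_DELIM_TAG:
                self.pos += 4
                break
            self.pos = save
            t, _, v = self.read_element()
            ds[t] = v
        return ds


def read_dicom(path) -> dict:
    """Parse an explicit-VR little-endian DICOM file into a tag dict."""
    with open(path, "rb") as fh:
        data = fh.read()
    pos = 0
    if len(data) > 132 and data[128:132] == b"DICM":
        pos = 132
    elif data[:4] != b"DICM":
        # allow headerless streams only if they start with a plausible tag
        if len(data) < 8:
            raise FormatError("file too short to be DICOM")
    reader = _Reader(data, pos)
    ds: dict = {}
    meta_end = None
    transfer_syntax = EXPLICIT_VR_LE
    while not reader.eof():
        if meta_end is not None and reader.pos >= meta_end and transfer_syntax != EXPLICIT_VR_LE:
            raise FormatError(
                f"unsupported transfer syntax {transfer_syntax!r}; only explicit "
                f"VR little endian ({EXPLICIT_VR_LE}) is supported"
            )
        tag, vr, value = reader.read_element()
        if tag == (0x0002, 0x0000):
            meta_end = reader.pos + int(value)
        if tag == (0x0002, 0x0010):
            transfer_syntax = value
        ds[tag] = value
    if transfer_syntax != EXPLICIT_VR_LE:
        raise FormatError(
            f"unsupported transfer syntax {transfer_syntax!r}; only explicit "
            f"VR little endian ({EXPLICIT_VR_LE}) is supported"
        )
    return ds


def _encode(vr: str, value: Any) -> bytes:
    if vr in _BINARY_FMT:
        fmt = _BINARY_FMT[vr]
        vals = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack(fmt, v) for v in vals)
    if vr in ("DS", "IS"):
        vals = value if isinstance(value, (list, tuple)) else [value]
        if vr == "DS":
            text = "\\".join(f"{float(v):.10g}" for v in vals)
        else:
            text = "\\".join(str(int(v)) for v in vals)
        raw = text.encode("ascii")
    elif vr in _TEXT_VRS:
        vals = value if isinstance(value, (list, tuple)) else [value]
        raw = "\\".join(str(v) for v in vals).encode("ascii")
    else:
        raw = bytes(value)
    if len(raw) % 2:
        raw += b"\x00" if vr in ("UI", "OB") else b" "
    return raw


def _write_element(out: bytearray, tag: tuple[int, int], vr: str, value: Any) -> None:
    if vr == "SQ":
        body = bytearray()
        for item in value:
            item_body = bytearray()
            for (t, item_vr, v) in item:
                _write_element(item_body, t, item_vr, v)
            body += struct.pack("<HHI", *ITEM_TAG, len(item_body))
            body += item_body
        out += struct.pack("<HH", *tag) + b"SQ" + b"\x00\x00" + struct.pack("<I", len(body))
        out += body
        return
    raw = _encode(vr, value)
    out += struct.pack("<HH", *tag) + vr.encode("ascii")
    if vr in _LONG_VRS:
        out += b"\x00\x00" + struct.pack("<I", len(raw))
    else:
        if len(raw) > 0xFFFF:
            raise FormatError(f"value too long for short VR {vr} at tag {tag}")
        out += struct.pack("<H", len(raw))
    out += raw


def write_dicom(path, elements: list[tuple[tuple[int, int], str, Any]], sop_class_uid: str) -> None:
    """Write elements (already sorted by tag) as explicit-VR LE with preamble."""
    meta = bytearray()
    meta_elements = [
        ((0x0002, 0x0002), "UI", sop_class_uid),
        ((0x0002, 0x0003), "UI", "2.25.0.1"),  # synthetic SOP instance UID
        ((0x0002, 0x0010), "UI", EXPLICIT_VR_LE),
    ]
    for tag, vr, value in meta_elements:
        _write_element(meta, tag, vr, value)
    body = bytearray()
    for tag, vr, value in elements:
        _write_element(body, tag, vr, value)
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        head = bytearray()
        _write_element(head, (0x0002, 0x0000), "UL", len(meta))
        fh.write(head)
        fh.write(meta)
        fh.write(body)
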