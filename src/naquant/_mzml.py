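"""Minimal reader for centroided mzML files.

Only the subset of mzML needed for direct-infusion centroid peak lists is
supported: MS1 spectra with base64-encoded 32/64-bit float m/z and intensity
arrays, optionally zlib-compressed. Profile-mode spectra are rejected.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET

import numpy as np

from .exceptions import FormatError, UnsupportedModeError

# PSI-MS controlled-vocabulary accessions
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(b64_text: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(b64_text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    itemsize = 8 if dtype == "f8" else 4
    if len(raw) % itemsize:
        raise FormatError("binary array length not a multiple of item size")
    n = len(raw) // itemsize
    fmt = "<" + ("d" if dtype == "f8" else "f") * n
    return np.asarray(struct.unpack(fmt, raw), dtype=np.float64)


def read_mzml_peaklists(path: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return one (mz, intensity) pair per spectrum in document order."""
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        context = ET.iterparse(path, events=("end",))
        for _, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            scans.append(_parse_spectrum(elem))
            elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"unparseable mzML file {path!r}: {exc}") from exc
    if not scans:
        raise FormatError(f"no spectra found in mzML file {path!r}")
    return scans


def _parse_spectrum(elem) -> tuple[np.ndarray, np.ndarray]:
    accessions = {
        child.get("accession")
        for child in elem.iter()
        if _local(child.tag) == "cvParam"
    }
    if _CV_PROFILE in accessions and _CV_CENTROID not in accessions:
        raise UnsupportedModeError(
            "profile-mode mzML spectrum without centroids is not supported"
        )
    mz = intensity = None
    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        kind = None
        dtype = "f8"
        compressed = False
        b64 = ""
        for child in bda:
            tag = _local(child.tag)
            if tag == "cvParam":
                acc = child.get("accession")
                if acc == _CV_MZ_ARRAY:
                    kind = "mz"
                elif acc == _CV_INTENSITY_ARRAY:
                    kind = "intensity"
                elif acc == _CV_FLOAT32:
                    dtype = "f4"
                elif acc == _CV_FLOAT64:
                    dtype = "f8"
                elif acc == _CV_ZLIB:
                    compressed = True
            elif tag == "binary":
                b64 = child.text or ""
        if kind is None:
            continue
        values = _decode_binary(b64, dtype, compressed)
        if kind == "mz":
            mz = values
        else:
            intensity = values
    if mz is None or intensity is None:
        raise FormatError("spectrum lacks m/z or intensity binary array")
    if mz.shape != intensity.shape:
        raise FormatError("m/z and intensity arrays differ in length")
    return mz, intensity
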