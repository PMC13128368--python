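"""Minimal NRRD read/write for dense 3D rasters.

Supports the subset of NRRD needed for atlas label volumes and density maps:
single detached-free files, ``raw`` or ``gzip`` encoding, little-endian,
integer or float types, with per-axis ``spacings`` (or diagonal ``space
directions``). Arrays are stored fastest-axis-first (Fortran order), matching
the convention of the common ``pynrrd`` package so files interoperate.
"""

from __future__ import annotations

import gzip
import zlib
from pathlib import Path

import numpy as np

_TYPE_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_TYPE = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64", np.dtype(np.uint64): "uint64",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


class NrrdFormatError(ValueError):
    """Raised when a file does not parse as the supported NRRD subset."""


def _parse_vector(text: str) -> list[float]:
    return [float(tok) for tok in text.replace("(", " ").replace(")", " ").replace(",", " ").split()]


def read(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file, returning ``(array, header)``.

    The array has shape ``sizes`` with the first NRRD axis as axis 0
    (Fortran-order memory layout, as pynrrd does).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise NrrdFormatError(f"{path}: not an NRRD file (magic {magic!r})")
        header: dict = {}
        while True:
            raw_line = fh.readline()
            if raw_line in (b"\n", b"\r\n", b""):
                break
            line = raw_line.decode("ascii", "replace").rstrip("\r\n")
            if line.startswith("#"):
                continue
            if ":=" in line:
                key, _, value = line.partition(":=")
            elif ":" in line:
                key, _, value = line.partition(":")
            else:
                raise NrrdFormatError(f"{path}: malformed header line {line!r}")
            header[key.strip().lower()] = value.strip()
        payload = fh.read()

    try:
        dim = int(header["dimension"])
        sizes = [int(s) for s in header["sizes"].split()]
        type_name = header["type"]
    except KeyError as exc:
        raise NrrdFormatError(f"{path}: missing required header field {exc}") from exc
    if len(sizes) != dim:
        raise NrrdFormatError(f"{path}: sizes {sizes} inconsistent with dimension {dim}")
    if type_name not in _TYPE_TO_DTYPE:
        raise NrrdFormatError(f"{path}: unsupported type {type_name!r}")
    endian = header.get("endian", "little")
    dtype = np.dtype(("<" if endian == "little" else ">") + _TYPE_TO_DTYPE[type_name])

    encoding = header.get("encoding", "raw")
    if encoding == "raw":
        buf = payload
    elif encoding in ("gzip", "gz"):
        try:
            buf = gzip.decompress(payload)
        except (OSError, zlib.error) as exc:
            raise NrrdFormatError(f"{path}: bad gzip payload: {exc}") from exc
    else:
        raise NrrdFormatError(f"{path}: unsupported encoding {encoding!r}")

    n_expect = int(np.prod(sizes))
    data = np.frombuffer(buf, dtype=dtype, count=n_expect)
    if data.size != n_expect:
        raise NrrdFormatError(f"{path}: expected {n_expect} elements, got {data.size}")
    array = data.reshape(sizes, order="F")

    parsed: dict = dict(header)
    if "spacings" in header:
        parsed["spacings"] = _parse_vector(header["spacings"])
    if "space directions" in header:
        rows = [r for r in header["space directions"].split(")") if r.strip()]
        mat = np.array([_parse_vector(r) for r in rows])
        parsed["space directions"] = mat
        off = mat - np.diag(np.diag(mat))
        if np.any(np.abs(off) > 1e-9):
            raise NrrdFormatError(f"{path}: non-diagonal space directions unsupported")
        parsed.setdefault("spacings", list(np.diag(mat)))
    return array, parsed


def write(path: str | Path, array: np.ndarray, spacings: list[float] | None = None,
          encoding: str = "raw", extra_header: dict | None = None) -> None:
    """Write ``array`` as NRRD. ``spacings`` are per-axis sample spacings."""
    path = Path(path)
    array = np.asarray(array)
    if array.dtype not in _DTYPE_TO_TYPE:
        raise NrrdFormatError(f"unsupported dtype {array.dtype}")
    if encoding not in ("raw", "gzip"):
        raise NrrdFormatError(f"unsupported encoding {encoding!r}")

    lines = [
        "NRRD0004",
        "# generated by cpmap",
        f"type: {_DTYPE_TO_TYPE[array.dtype]}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacings is not None:
        if len(spacings) != array.ndim:
            raise NrrdFormatError("spacings length must match array.ndim")
        lines.append("spacings: " + " ".join(repr(float(s)) for s in spacings))
    for key, value in (extra_header or {}).items():
        lines.append(f"{key}: {value}")

    buf = np.asfortranarray(array).astype(array.dtype.newbyteorder("<"), copy=False).tobytes(order="F")
    if encoding == "gzip":
        # mtime pinned so identical arrays give byte-identical files
        buf = gzip.compress(buf, mtime=0)
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(buf)
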