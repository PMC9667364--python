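"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Supports the subset of NRRD needed for segmented label volumes: 3D arrays,
`raw` and `gzip` encodings, little/big endian scalar types, and the
``spacings`` / ``space directions`` header fields from which physical voxel
spacing is recovered.  Detached data files are not supported.
"""
from __future__ import annotations

import gzip
import io
from pathlib import Path

import numpy as np

_TYPE_MAP = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "short int": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}


def _parse_vector(text: str) -> list[float]:
    return [float(v) for v in text.strip().lstrip("(").rstrip(")").split(",")]


def read(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file; return ``(array, header)``.

    ``header['spacings']`` holds the per-axis physical spacing when the file
    declares either a ``spacings`` line or axis-aligned ``space directions``.
    """
    path = Path(path)
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or end < 0:
        raise ValueError(f"{path} is not a valid NRRD file")
    header: dict = {}
    for line in raw[:end].decode("ascii", errors="replace").splitlines()[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        header[key.strip().lower()] = value.lstrip("=").strip()

    dtype_key = header.get("type", "")
    if dtype_key not in _TYPE_MAP:
        raise ValueError(f"unsupported NRRD type {dtype_key!r}")
    endian = ">" if header.get("endian", "little") == "big" else "<"
    dtype = np.dtype(endian + _TYPE_MAP[dtype_key])
    sizes = [int(s) for s in header.get("sizes", "").split()]
    if not sizes:
        raise ValueError("NRRD header missing sizes")

    encoding = header.get("encoding", "raw")
    body = raw[end + 2:]
    if encoding in ("gzip", "gz"):
        body = gzip.decompress(body)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(body, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD stores the fastest-varying axis first (Fortran order).
    array = data.reshape(sizes[::-1]).transpose(range(len(sizes))[::-1])

    spacings = None
    if "spacings" in header:
        spacings = [float(v) for v in header["spacings"].split()]
    elif "space directions" in header:
        vecs = [
            _parse_vector(tok)
            for tok in header["space directions"].split(")")
            if tok.strip(" (")
        ]
        spacings = [float(np.linalg.norm(v)) for v in vecs]
    header["spacings"] = spacings
    return np.ascontiguousarray(array), header


def write(path: str | Path, array: np.ndarray, spacings=None, encoding: str = "gzip") -> None:
    """Write a 3D array as NRRD (gzip or raw encoding)."""
    array = np.asarray(array)
    inverse = {v: k for k, v in _TYPE_MAP.items()}
    code = array.dtype.str.lstrip("<>|=")
    if code not in inverse:
        raise ValueError(f"cannot encode dtype {array.dtype}")
    lines = [
        "NRRD0004",
        f"type: {inverse[code]}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacings is not None:
        lines.append(f"spacings: {' '.join(repr(float(s)) for s in spacings)}")
    body = np.ascontiguousarray(array.transpose(range(array.ndim)[::-1]),
                                dtype=array.dtype.newbyteorder("<")).tobytes()
    if encoding == "gzip":
        body = gzip.compress(body)
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with io.open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(body)
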