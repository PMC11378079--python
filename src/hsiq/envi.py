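"""Minimal ENVI-format I/O for hyperspectral cubes.

Writes a plain-text ``.hdr`` plus a raw binary file (float32, BSQ by
default) and reads BSQ/BIL/BIP interleaves with the numeric data types used
in practice.  Covers the interchange subset needed here; band-math headers,
map info and esoteric fields are ignored on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_envi", "read_envi"]

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_envi(path, data: np.ndarray, wavelengths=None, interleave="bsq",
               dtype=np.float32):
    """Write (rows, cols, bands) data to <path>.hdr / <path>.dat."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("expected a (rows, cols, bands) array")
    rows, cols, bands = data.shape
    dtype = np.dtype(dtype)
    if dtype not in _CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    interleave = interleave.lower()
    if interleave == "bsq":
        raw = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        raw = np.transpose(data, (0, 2, 1))
    elif interleave == "bip":
        raw = data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    raw.astype(dtype).tofile(path.with_suffix(".dat"))
    lines = [
        "ENVI",
        "description = {hsiq data cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths).ravel())
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = {" + wl + "}")
    path.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


def _parse_header(text: str) -> dict:
    fields = {}
    key = None
    buf = ""
    in_braces = False
    for line in text.splitlines():
        if in_braces:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf.split("{", 1)[1].rsplit("}", 1)[0].strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf = val
            in_braces = True
        elif val.startswith("{"):
            fields[key] = val.split("{", 1)[1].rsplit("}", 1)[0].strip()
        else:
            fields[key] = val
    return fields


def read_envi(path):
    """Read <path>.hdr / <path>.dat; returns (data, wavelengths_or_None).

    Data is returned as float64 (rows, cols, bands).
    """
    path = Path(path)
    hdr = _parse_header(path.with_suffix(".hdr").read_text())
    rows = int(hdr["lines"])
    cols = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = _DTYPES[int(hdr["data type"])]
    interleave = hdr.get("interleave", "bsq").lower()
    offset = int(hdr.get("header offset", 0))
    raw = np.fromfile(path.with_suffix(".dat"), dtype=dtype, offset=offset)
    if raw.size != rows * cols * bands:
        raise ValueError("raw file size does not match header dimensions")
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl = None
    if "wavelength" in hdr:
        wl = np.array([float(v) for v in hdr["wavelength"].split(",")])
    return np.ascontiguousarray(data, dtype=float), wl
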