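"""Minimal ENVI-style raster I/O for hypercubes.

An ENVI raster is a pair of files: a plain-text ``.hdr`` header holding
``samples``/``lines``/``bands``, the interleave, the data type and the
wavelength list, and a headerless binary file with the raw array.  BIL is
written; BIL, BIP and BSQ are accepted on read.  Only the header fields a
laboratory pipeline needs are honored; vendor extensions are ignored.
"""

from __future__ import annotations

import os
import re

import numpy as np

# ENVI "data type" codes -> numpy dtypes (little-endian assumed, byte order 0)
_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def _header_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path
    return path + ".hdr"


def _data_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path[: -len(".hdr")]
    return path


def read_header(path: str) -> dict:
    """Parse an ENVI text header into a dict of lowercase keys."""
    text = open(_header_path(path)).read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header (missing ENVI magic)")
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            items = [v.strip() for v in val.strip("{}").split(",") if v.strip()]
            fields[key] = items
        else:
            fields[key] = val
    return fields


def read_cube(path: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI raster; return (lines x samples x bands array, wavelengths).

    The array is returned band-interleaved-by-pixel in memory regardless of
    the file interleave; wavelengths is None when the header carries none.
    """
    hdr = read_header(path)
    try:
        lines = int(hdr["lines"])
        samples = int(hdr["samples"])
        bands = int(hdr["bands"])
        dtype = np.dtype(_DTYPES[int(hdr["data type"])])
    except KeyError as e:
        raise ValueError(f"{path}: ENVI header missing required field {e}") from e
    interleave = str(hdr.get("interleave", "bil")).lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"{path}: unsupported interleave '{interleave}'")

    raw = np.fromfile(_data_path(path), dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"{path}: raster holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bil":            # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":          # (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    else:                              # bsq: (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    wav = hdr.get("wavelength")
    wavelengths = np.array([float(w) for w in wav]) if wav is not None else None
    if wavelengths is not None and wavelengths.size != bands:
        raise ValueError(f"{path}: wavelength list length != bands")
    return np.ascontiguousarray(data), wavelengths


def write_cube(path: str, data: np.ndarray,
               wavelengths: np.ndarray | None = None,
               dtype=np.float32) -> None:
    """Write a lines x samples x bands array as an ENVI raster, BIL interleave."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("write_cube expects a lines x samples x bands array")
    dtype = np.dtype(dtype)
    if dtype not in _CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    lines, samples, bands = data.shape
    if wavelengths is not None and len(wavelengths) != bands:
        raise ValueError("wavelength list length != bands")

    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    body = data.astype(dtype).transpose(0, 2, 1)  # -> BIL on disk
    body.tofile(_data_path(path))

    hdr_lines = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[dtype]}",
        "interleave = bil",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.6f}" for w in wavelengths)
        hdr_lines.append("wavelength units = Nanometers")
        hdr_lines.append("wavelength = {%s}" % wl)
    with open(_header_path(path), "w") as fh:
        fh.write("\n".join(hdr_lines) + "\n")
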