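"""ENVI hyperspectral cube I/O and lamp normalization.

The ENVI container is an ASCII ``key = value`` header next to a raw binary
array.  Three interleaves are supported: BSQ (band-sequential), BIL
(band-interleaved-by-line) and BIP (band-interleaved-by-pixel).  In memory a
cube is always band-last (rows, cols, bands); the interleave is purely an
I/O concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidGridError, InvalidReferenceError, UnsupportedFormatError
from .spectral_core import WavelengthGrid

__all__ = ["HyperCube", "read_envi", "write_envi", "lamp_normalize"]

# ENVI numeric "data type" codes <-> numpy dtypes (the subset we support)
_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """A hyperspectral image: (height, width, bands) intensities on a grid."""

    data: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got {self.data.ndim}-D")
        if self.data.shape[2] != self.grid.n_samples:
            raise InvalidGridError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _parse_header(text: str) -> dict:
    """Parse ENVI header text into a {key: str-or-list} dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise UnsupportedFormatError("missing ENVI magic line in header")
    body = text.lstrip()[4:]
    fields: dict = {}
    # fold brace-delimited multi-line values onto one line first
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            inner = value.strip("{} ")
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = value
    return fields


def read_envi(header_path, data_path=None) -> HyperCube:
    """Read an ENVI cube (header + raw binary) into a band-last array.

    ``data_path`` defaults to the header path with the ``.hdr`` suffix
    removed (or replaced by nothing), mirroring the usual export layout.
    The header must carry a uniform ``wavelength`` list; a non-uniform axis
    is an error, never silently resampled.
    """
    header_path = Path(header_path)
    if data_path is None:
        stem = header_path.with_suffix("")
        candidates = [stem] + [stem.with_suffix(ext) for ext in (".raw", ".img", ".dat")]
        data_path = next((p for p in candidates if p.exists() and p != header_path), None)
        if data_path is None:
            raise FileNotFoundError("data_path not given and could not be inferred")
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])  # columns
        lines = int(fields["lines"])  # rows
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = str(fields["interleave"]).lower()
    except KeyError as exc:
        raise UnsupportedFormatError(f"header missing required field: {exc}") from exc

    if interleave not in _INTERLEAVES:
        raise UnsupportedFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPE_CODES:
        raise UnsupportedFormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in fields:
        raise InvalidGridError("header has no wavelength list; supply one explicitly")
    grid = WavelengthGrid.from_values([float(w) for w in fields["wavelength"]])
    if grid.n_samples != bands:
        raise InvalidGridError(f"{bands} bands but {grid.n_samples} wavelengths")

    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise UnsupportedFormatError(
            f"data file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        cube = raw.reshape(lines, samples, bands)
    return HyperCube(np.ascontiguousarray(cube), grid)


def write_envi(cube: HyperCube, header_path, data_path, interleave: str = "bsq") -> None:
    """Write a cube as ENVI header + raw binary in the requested interleave.

    Floating cubes are written as float32 (ENVI type 4) by default of the
    array's own dtype; integer dtypes round-trip bit-exactly.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise UnsupportedFormatError(f"unsupported interleave {interleave!r}")
    data = cube.data
    dtype = np.dtype(data.dtype)
    if dtype not in _CODE_FOR_DTYPE:
        dtype = np.dtype(np.float32)
        data = data.astype(dtype)
    code = _CODE_FOR_DTYPE[dtype]

    lines, samples, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    wavelengths = ", ".join(f"{w:.10f}" for w in cube.grid.values)
    header = (
        "ENVI\n"
        "description = {hsmad export}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    Path(header_path).write_text(header)
    np.ascontiguousarray(out).astype(dtype.newbyteorder("<")).tofile(data_path)


def lamp_normalize(cube: HyperCube, reference) -> HyperCube:
    """Divide every pixel spectrum band-wise by the lamp reference spectrum.

    Raises
    ------
    InvalidReferenceError
        If any reference band is zero or negative.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (cube.n_bands,):
        raise InvalidReferenceError(
            f"reference has shape {reference.shape}, cube has {cube.n_bands} bands"
        )
    if np.any(reference <= 0):
        raise InvalidReferenceError("lamp reference must be strictly positive")
    return HyperCube(cube.data / reference, cube.grid)
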