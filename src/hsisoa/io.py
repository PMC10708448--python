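"""Hyperspectral cube containers, ENVI-format I/O and flat-field calibration.

A line-scan camera records one spatial line (``samples`` pixels) times
``bands`` wavelengths per frame; scanning stacks frames into a cube of
shape (rows, cols, bands).  Raw digital numbers (DN) are converted to
reflectance against dark-current and white-reference frames:

    R = (DN_raw - DN_dark) / (DN_white - DN_dark)

The references may be full frames, per-line arrays (cols x bands) or
scalars; anything numpy can broadcast against the cube is accepted.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "HyperCube",
    "ReferenceFrames",
    "read_envi",
    "write_envi",
    "calibrate",
]

# ENVI numeric codes for the dtypes this package reads and writes.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")

# Metadata keys propagated through I/O and calibration.
_META_KEYS = ("sample_id", "treatment", "soa", "moa_group", "dat", "round")


@dataclass
class HyperCube:
    """A hyperspectral image: ``data[rows, cols, bands]`` plus its wavelength grid.

    ``kind`` distinguishes raw DN cubes from calibrated reflectance;
    ``meta`` carries acquisition metadata (sample id, treatment, days
    after treatment, round) untouched through every pipeline step.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """Dark and white calibration frames, broadcastable against a cube."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)


def _format_header(cube: HyperCube, interleave: str, dtype_code: int) -> str:
    rows, cols, bands = cube.shape
    lines = [
        "ENVI",
        "description = {hsisoa hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {dtype_code}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{w:.6f}" for w in cube.wavelengths) + "}",
        f"cube kind = {cube.kind}",
    ]
    for key in _META_KEYS:
        if key in cube.meta and cube.meta[key] is not None:
            lines.append(f"{key} = {cube.meta[key]}")
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    # Join brace-delimited multi-line values, then split on '='.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_envi(cube: HyperCube, path: str, interleave: str = "bil") -> None:
    """Write ``cube`` as an ENVI data file at ``path`` with header ``path + '.hdr'``."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unknown interleave {interleave!r}; expected one of {_INTERLEAVES}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype} for ENVI export")
    arr = cube.data
    if interleave == "bil":        # lines, bands, samples
        ordered = np.transpose(arr, (0, 2, 1))
    elif interleave == "bip":      # lines, samples, bands
        ordered = arr
    else:                          # bsq: bands, lines, samples
        ordered = np.transpose(arr, (2, 0, 1))
    np.ascontiguousarray(ordered).tofile(path)
    with open(path + ".hdr", "w") as fh:
        fh.write(_format_header(cube, interleave, _DTYPE_CODES[dtype]))


def read_envi(path: str) -> HyperCube:
    """Read an ENVI image (data file plus ``.hdr`` sidecar) into a :class:`HyperCube`."""
    hdr_path = path + ".hdr" if os.path.exists(path + ".hdr") else path
    if hdr_path == path and path.endswith(".hdr"):
        path = path[: -len(".hdr")]
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unknown interleave {fields['interleave']!r}")

    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )

    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"data file holds {raw.size} values; header implies {rows * cols * bands}"
        )
    if interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)

    meta: dict[str, Any] = {}
    for key in _META_KEYS:
        if key in fields:
            value: Any = fields[key]
            if key in ("dat", "round"):
                value = int(value)
            meta[key] = value
    kind = fields.get("cube kind", "raw")
    return HyperCube(data=data.copy(), wavelengths=wavelengths, kind=kind, meta=meta)


def calibrate(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Flat-field calibration ``R = (raw - dark) / (white - dark)``.

    The result is gain-invariant: multiplying raw, dark and white by a
    common (possibly per-pixel) illumination factor leaves R unchanged,
    which is what removes line-scan light-source non-uniformity.
    Out-of-range values (<0 or >1) are kept, not clipped.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate expects a raw-DN cube")
    try:
        denom = np.broadcast_to(refs.white - refs.dark, raw.shape)
    except ValueError as exc:
        raise ValueError(
            f"reference frames of shape dark{refs.dark.shape}/white{refs.white.shape} "
            f"do not broadcast against cube shape {raw.shape}"
        ) from exc
    bad = denom <= 0
    if np.any(bad):
        pix = np.unravel_index(int(np.argmax(bad)), raw.shape)
        raise ValueError(
            "white - dark is non-positive at pixel "
            f"(row={pix[0]}, col={pix[1]}, band={pix[2]}, "
            f"wavelength={raw.wavelengths[pix[2]]:.1f} nm)"
        )
    data = (raw.data.astype(float) - refs.dark) / denom
    return HyperCube(
        data=data,
        wavelengths=raw.wavelengths.copy(),
        kind="reflectance",
        meta=dict(raw.meta),
    )
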