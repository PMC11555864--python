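"""Hyperspectral datacube container, ENVI I/O, and pre-classification pixel hygiene.

A rhizobox scene is recorded as an H x W x B reflectance datacube with a
wavelength axis (here nominally 150 bands over 470-900 nm). Before any
classification, pixels go through three hygiene steps: conversion of raw
digital numbers to reflectance against white/dark reference frames, masking
of overexposed pixels (any reflectance value above 1 zeroes the whole pixel
spectrum), and optional spatial binning/cropping.

ENVI files are an ASCII ``.hdr`` (key = value, lists in braces) next to a flat
binary cube; BSQ, BIL and BIP interleaves are read, BSQ is written.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "Wavelengths",
    "Datacube",
    "ReferenceSet",
    "read_envi",
    "write_envi",
    "reflectance_correct",
    "mask_overexposed",
    "spatial_bin",
    "crop",
]

DEFAULT_BAND_COUNT = 150
DEFAULT_RANGE_NM = (470.0, 900.0)


@dataclass(frozen=True)
class Wavelengths:
    """Strictly increasing band-center wavelengths in nanometres."""

    values_nm: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values_nm, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength axis needs at least 2 band centers")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values_nm", values)

    @property
    def count(self) -> int:
        return int(self.values_nm.size)

    @classmethod
    def default(cls, bands: int = DEFAULT_BAND_COUNT) -> "Wavelengths":
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, bands))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Wavelengths):
            return NotImplemented
        return np.array_equal(self.values_nm, other.values_nm)


@dataclass
class Datacube:
    """H x W x B reflectance cube with pixel mask and acquisition metadata.

    ``pixel_mask`` is True for usable pixels; masked-out pixels carry all-zero
    spectra. ``meta`` is a free-form acquisition record (configuration id,
    binning factor, physical width/height in mm, ...).
    """

    data: np.ndarray
    wavelengths: Wavelengths
    pixel_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"cube must be H x W x B, got shape {data.shape}")
        if data.shape[2] != self.wavelengths.count:
            raise ValueError(
                f"band axis ({data.shape[2]}) disagrees with wavelength "
                f"count ({self.wavelengths.count})"
            )
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("cube must have at least one pixel")
        self.data = data
        if self.pixel_mask is None:
            self.pixel_mask = np.ones(data.shape[:2], dtype=bool)
        else:
            mask = np.asarray(self.pixel_mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValueError("pixel_mask shape must match spatial dims")
            self.pixel_mask = mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def spectra_2d(self) -> np.ndarray:
        """Pixels flattened row-major to an (H*W, B) matrix."""
        h, w, b = self.data.shape
        return self.data.reshape(h * w, b)

    def copy(self) -> "Datacube":
        return Datacube(
            self.data.copy(),
            self.wavelengths,
            self.pixel_mask.copy(),
            dict(self.meta),
        )


@dataclass
class ReferenceSet:
    """Raw digital numbers plus white/dark reference frames.

    ``white``/``dark`` may be full H x W x B frames or per-band vectors; the
    white target has a known reflectance (0.95 for the reference panel used
    at acquisition).
    """

    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    target_reflectance: float = 0.95
    wavelengths: Wavelengths | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.raw.ndim != 3:
            raise ValueError("raw must be an H x W x B cube")
        if not 0 < self.target_reflectance <= 1:
            raise ValueError("target_reflectance must be in (0, 1]")
        np.broadcast_shapes(self.raw.shape, self.white.shape, self.dark.shape)


# ---------------------------------------------------------------------------
# ENVI I/O

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    # join brace-delimited multi-line values before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _header_path(path: Path) -> tuple[Path, Path]:
    """Resolve (header, binary) from either member of an ENVI pair."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        hdr = path
        for ext in (".img", ".dat", ".raw", ""):
            cand = path.with_suffix(ext)
            if cand.exists() and cand != hdr:
                return hdr, cand
        raise FileNotFoundError(f"no binary cube found next to {hdr}")
    hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        hdr = Path(str(path) + ".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    return hdr, path


def read_envi(path: str | Path) -> Datacube:
    """Read an ENVI header + binary pair into a :class:`Datacube`.

    ``path`` may point at the ``.hdr`` or at the binary. All three
    interleaves (BSQ/BIL/BIP) are accepted; wavelength metadata is required.
    """
    hdr_path, bin_path = _header_path(Path(path))
    fields = _parse_envi_header(hdr_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength metadata")

    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = Wavelengths(
        np.array([float(v) for v in wl_text.split(",") if v.strip()])
    )
    if wavelengths.count != bands:
        raise ValueError("wavelength list length disagrees with band count")

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))
    interleave = fields.get("interleave", "bsq").lower()

    expected = lines * samples * bands
    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    if raw.size != expected:
        raise ValueError(
            f"binary cube holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    meta: dict[str, Any] = {"source": str(bin_path)}
    sidecar = bin_path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Datacube(np.ascontiguousarray(data), wavelengths, meta=meta)


def write_envi(cube: Datacube, path: str | Path) -> Path:
    """Write ``cube`` as float32 BSQ ENVI (``path``.img + ``path``.hdr).

    Cube metadata is echoed to a JSON sidecar next to the binary. Returns the
    header path.
    """
    path = Path(path)
    if path.suffix.lower() in {".hdr", ".img"}:
        path = path.with_suffix("")
    bin_path = path.with_suffix(".img")
    hdr_path = path.with_suffix(".hdr")

    h, w, b = cube.shape
    cube.data.astype(np.float32).transpose(2, 0, 1).tofile(bin_path)
    wl = ", ".join(repr(float(v)) for v in cube.wavelengths.values_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    sidecar = bin_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(_jsonable(cube.meta), indent=2, sort_keys=True) + "\n"
    )
    return hdr_path


def _jsonable(meta: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in meta.items():
        if isinstance(value, np.generic):
            value = value.item()
        elif isinstance(value, np.ndarray):
            value = value.tolist()
        out[key] = value
    return out


# ---------------------------------------------------------------------------
# Pixel hygiene

def reflectance_correct(refs: ReferenceSet) -> Datacube:
    """Convert raw digital numbers to reflectance against white/dark frames.

    R = target_reflectance * (raw - dark) / (white - dark), band-wise. Bands
    whose white and dark frames coincide everywhere are flagged unusable in
    ``meta['unusable_bands']``; values are deliberately NOT clipped —
    overexposure is handled downstream by :func:`mask_overexposed`.
    """
    span = refs.white - refs.dark
    degenerate = span == 0

    bands = refs.raw.shape[2]
    span_b = np.broadcast_to(span, refs.raw.shape)
    unusable = [
        b for b in range(bands) if np.all(span_b[:, :, b] == 0)
    ]
    if len(unusable) == bands:
        raise ValueError("white and dark references coincide on every band")

    with np.errstate(divide="ignore", invalid="ignore"):
        reflectance = refs.target_reflectance * (refs.raw - refs.dark) / span
    reflectance = np.where(np.broadcast_to(degenerate, reflectance.shape),
                           0.0, reflectance)

    wavelengths = refs.wavelengths or Wavelengths.default(bands)
    meta = {
        "reflectance_target": refs.target_reflectance,
        "unusable_bands": unusable,
    }
    return Datacube(reflectance, wavelengths, meta=meta)


def mask_overexposed(cube: Datacube) -> Datacube:
    """Zero and mask every pixel whose spectrum exceeds reflectance 1.

    A single overexposed band invalidates the pixel: its entire spectrum is
    set to 0 and ``pixel_mask`` cleared, so downstream angle and derivative
    computations never see a partially clipped spectrum. The count of newly
    masked pixels is recorded in ``meta['n_overexposed_masked']``.
    """
    out = cube.copy()
    overexposed = (out.data > 1.0).any(axis=2) & out.pixel_mask
    out.data[overexposed] = 0.0
    out.pixel_mask &= ~overexposed
    # keep previously-masked pixels zeroed as per the Datacube invariant
    out.data[~out.pixel_mask] = 0.0
    out.meta["n_overexposed_masked"] = int(overexposed.sum())
    return out


def spatial_bin(cube: Datacube, factor: int) -> Datacube:
    """Average non-overlapping factor x factor pixel blocks per band.

    Trailing rows/columns that do not fill a block are dropped (sensor-style
    binning). Output mask is True only where every source pixel in the block
    was usable; physical-dimension metadata is carried over unchanged.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("binning factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return cube.copy()
    h, w, b = cube.shape
    hb, wb = h // factor, w // factor
    if hb < 1 or wb < 1:
        raise ValueError("cube smaller than one binning block")
    trimmed = cube.data[: hb * factor, : wb * factor]
    blocks = trimmed.reshape(hb, factor, wb, factor, b)
    binned = blocks.mean(axis=(1, 3))
    mask = (
        cube.pixel_mask[: hb * factor, : wb * factor]
        .reshape(hb, factor, wb, factor)
        .all(axis=(1, 3))
    )
    binned[~mask] = 0.0
    meta = dict(cube.meta)
    meta["binning_factor"] = factor * meta.get("binning_factor", 1)
    return Datacube(binned, cube.wavelengths, mask, meta)


def crop(cube: Datacube, row0: int, col0: int, height: int, width: int) -> Datacube:
    """Extract a sub-cube; 0-based, origin top-left, half-open window."""
    h, w, _ = cube.shape
    if row0 < 0 or col0 < 0 or height < 1 or width < 1:
        raise ValueError("crop window must be positive and within bounds")
    if row0 + height > h or col0 + width > w:
        raise ValueError(
            f"crop window [{row0}:{row0 + height}, {col0}:{col0 + width}] "
            f"exceeds cube extent {h} x {w}"
        )
    meta = dict(cube.meta)
    meta["crop_window"] = [row0, col0, height, width]
    return Datacube(
        cube.data[row0 : row0 + height, col0 : col0 + width].copy(),
        cube.wavelengths,
        cube.pixel_mask[row0 : row0 + height, col0 : col0 + width].copy(),
        meta,
    )
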