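"""Spectral dimension reduction by second-derivative extrema.

The 150-band spectra are reduced to a handful of informative wavelengths by
(1) taking the Savitzky-Golay second derivative of each image's root-class
mean spectrum (default window 21 bands, cubic fit — the window that filters
noise without over-smoothing genuine absorption features), (2) averaging the
derivative curves across images, and (3) keeping the local peaks and troughs
of the averaged curve. The second derivative suppresses additive offsets and
linear baseline drift, so its extrema sit on genuine curvature features of
the reflectance spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "DerivativeSet",
    "BandSelection",
    "savgol_second_derivative",
    "compare_windows",
    "average_d2",
    "select_bands",
]

DEFAULT_WINDOW = 21
DEFAULT_POLYORDER = 3


def _check_window(window: int, polyorder: int, n_bands: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > n_bands:
        raise ValueError(f"window {window} exceeds band count {n_bands}")
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")


@dataclass
class DerivativeSet:
    """Second-derivative curves of root-class mean spectra, one per image."""

    curves: dict[str, np.ndarray]
    window: int = DEFAULT_WINDOW
    polyorder: int = DEFAULT_POLYORDER

    def __post_init__(self) -> None:
        self.curves = {k: np.asarray(v, dtype=float) for k, v in self.curves.items()}
        lengths = {v.size for v in self.curves.values()}
        if len(lengths) > 1:
            raise ValueError("derivative curves must share one band axis")
        if self.curves:
            _check_window(self.window, self.polyorder, next(iter(lengths)))

    @classmethod
    def from_spectra(
        cls,
        spectra: Mapping[str, np.ndarray],
        window: int = DEFAULT_WINDOW,
        polyorder: int = DEFAULT_POLYORDER,
    ) -> "DerivativeSet":
        curves = {
            image_id: savgol_second_derivative(s, window, polyorder)
            for image_id, s in spectra.items()
        }
        return cls(curves, window, polyorder)


@dataclass
class BandSelection:
    """Retained band indices with their wavelengths and provenance."""

    indices: np.ndarray
    wavelengths_nm: np.ndarray
    kinds: tuple[str, ...] = ()  # "peak" | "trough" per index
    source: str = ""
    mean_d2: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and not np.all(np.diff(idx) > 0):
            raise ValueError("band indices must be strictly increasing")
        if np.any(idx < 0):
            raise ValueError("band indices must be non-negative")
        self.indices = idx
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.size != idx.size:
            raise ValueError("wavelengths must match selected indices")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "band_index": self.indices,
                "kind": list(self.kinds) or [""] * len(self),
            }
        )


def savgol_second_derivative(
    spectrum: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    spacing: float = 1.0,
) -> np.ndarray:
    """Second derivative of the local least-squares polynomial fit.

    ``spacing`` is in band-index units by default (windows are quoted in
    "wavelengths", i.e. bands). Edges are handled by fitting the polynomial on
    the one-sided truncated window, which avoids inventing data beyond the
    recorded range; edge values are therefore less smoothed than interior
    ones. Exact for polynomial inputs up to ``polyorder``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    _check_window(window, polyorder, spectrum.size)
    return savgol_filter(
        spectrum, window, polyorder, deriv=2, delta=spacing, mode="interp"
    )


def compare_windows(
    spectra: Mapping[str, np.ndarray],
    windows: Sequence[int],
    polyorder: int = DEFAULT_POLYORDER,
) -> pd.DataFrame:
    """Second-derivative curves for each (spectrum, window) pair.

    Returns a long table (image_id, window, band_index, d2, roughness) where
    roughness is the per-curve sum of squared successive differences — a
    scalar aid for choosing the window: small windows keep noise artifacts
    (high roughness), windows past ~25 bands over-smooth genuine signals.
    """
    frames = []
    for window in windows:
        for image_id, spectrum in spectra.items():
            d2 = savgol_second_derivative(spectrum, window, polyorder)
            roughness = float(np.sum(np.diff(d2) ** 2))
            frames.append(
                pd.DataFrame(
                    {
                        "image_id": image_id,
                        "window": window,
                        "band_index": np.arange(d2.size),
                        "d2": d2,
                        "roughness": roughness,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def average_d2(dset: DerivativeSet) -> np.ndarray:
    """Band-wise arithmetic mean of the per-image derivative curves."""
    if not dset.curves:
        raise ValueError("empty derivative set")
    return np.mean(list(dset.curves.values()), axis=0)


def _local_extrema(curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior strict local maxima and minima (plateau-tolerant on the left)."""
    maxima, minima = [], []
    for i in range(1, curve.size - 1):
        left, here, right = curve[i - 1], curve[i], curve[i + 1]
        if here > left and here > right:
            maxima.append(i)
        elif here < left and here < right:
            minima.append(i)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def select_bands(
    mean_d2: np.ndarray,
    wavelengths_nm: np.ndarray | None = None,
    min_prominence_frac: float = 0.05,
    min_separation_bands: int = 3,
    source: str = "",
) -> BandSelection:
    """Pick peaks and troughs of the averaged second-derivative curve.

    Local extrema with |value| >= min_prominence_frac * max|curve| are kept,
    then thinned so selected indices sit >= min_separation_bands apart
    (larger |value| wins; ties go to the lower index). Scale-invariant: the
    prominence cut is relative to the curve's own amplitude. An all-zero
    curve yields a valid empty selection.
    """
    curve = np.asarray(mean_d2, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("derivative curve must be finite")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(curve.size, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size != curve.size:
        raise ValueError("wavelength axis must match curve length")

    amplitude = np.max(np.abs(curve)) if curve.size else 0.0
    params = {
        "min_prominence_frac": min_prominence_frac,
        "min_separation_bands": min_separation_bands,
    }
    if amplitude == 0.0:
        return BandSelection(
            np.array([], dtype=int), np.array([]), (), source, curve, params
        )

    maxima, minima = _local_extrema(curve)
    candidates = [(int(i), "peak") for i in maxima] + [
        (int(i), "trough") for i in minima
    ]
    threshold = min_prominence_frac * amplitude
    candidates = [
        (i, kind) for i, kind in candidates if abs(curve[i]) >= threshold
    ]
    # greedy thinning: strongest first, ties to the lower index
    candidates.sort(key=lambda ik: (-abs(curve[ik[0]]), ik[0]))
    kept: list[tuple[int, str]] = []
    for i, kind in candidates:
        if all(abs(i - j) >= min_separation_bands for j, _ in kept):
            kept.append((i, kind))
    kept.sort()
    indices = np.array([i for i, _ in kept], dtype=int)
    kinds = tuple(kind for _, kind in kept)
    return BandSelection(
        indices, wavelengths_nm[indices], kinds, source, curve, params
    )
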