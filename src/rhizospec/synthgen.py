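"""Synthetic rhizobox hyperspectral scenes with ground truth.

Real rhizobox cubes are large and rarely shareable, so every pipeline stage
is exercised against generated scenes instead: biased random-walk root
strands drawn from the top edge (roots grow downward along the observation
panel), a morphological halo around them standing in for the root-soil
interface/rhizosheath, and the remainder soil. Each class renders a smooth
endmember spectrum on the 470-900 nm grid — soil low and gently rising,
root brighter with a sigmoidal red-edge rise to a NIR plateau, interface a
linear mixture of the two — corrupted by independent per-pixel-per-band
additive and multiplicative Gaussian noise. Scenes are bit-reproducible for
a fixed parameter set (seed included) and ship their own ground-truth class
map and sampled ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from skimage.morphology import dilation as _gray_dilation, disk


def _binary_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    return _gray_dilation(mask, disk(radius)).astype(bool)

from .classify import CLASS_IDS, CLASS_NAMES, ClassMap, ROISet
from .cube_io import Datacube, Wavelengths

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "endmember_spectra",
    "draw_root_mask",
    "make_scene",
    "species_presets",
    "absorption_signal",
    "root_spectra_with_features",
]


@dataclass(frozen=True)
class SceneParams:
    """Everything that defines a synthetic scene, including its seed."""

    height: int = 120
    width: int = 160
    bands: int = 150
    wavelength_range_nm: tuple[float, float] = (470.0, 900.0)
    # root geometry
    n_roots: int = 3
    step_bias: float = 0.8  # probability of a downward step
    branch_prob: float = 0.03
    root_dilation_px: int = 2
    halo_radius_px: int = 3
    # endmembers
    soil_base: float = 0.12
    soil_slope: float = 0.10  # total rise over the wavelength range
    root_base: float = 0.25
    red_edge_center_nm: float = 700.0
    red_edge_width_nm: float = 30.0
    nir_amplitude: float = 0.35
    interface_alpha_range: tuple[float, float] = (0.3, 0.7)
    # noise / defects
    sigma_additive: float = 0.01
    sigma_multiplicative: float = 0.03
    overexposure_fraction: float = 0.0
    # sampling
    roi_pixels: int = 150
    seed: int = 0
    physical_width_mm: float = 115.0
    physical_height_mm: float = 155.0

    def __post_init__(self) -> None:
        if self.bands < 4:
            raise ValueError("need at least 4 bands")
        lo, hi = self.wavelength_range_nm
        if not lo < hi:
            raise ValueError("degenerate wavelength range")
        if self.root_dilation_px < 0 or self.halo_radius_px < 0:
            raise ValueError("radii must be non-negative")
        if self.sigma_additive < 0 or self.sigma_multiplicative < 0:
            raise ValueError("noise levels must be non-negative")
        a0, a1 = self.interface_alpha_range
        if not (0 < a0 <= a1 < 1):
            raise ValueError("mixing fractions must lie in (0, 1)")
        if not 0 <= self.overexposure_fraction < 1:
            raise ValueError("overexposure fraction must lie in [0, 1)")

    @property
    def wavelengths(self) -> Wavelengths:
        lo, hi = self.wavelength_range_nm
        return Wavelengths(np.linspace(lo, hi, self.bands))


@dataclass
class SyntheticScene:
    """Rendered cube + ground-truth class map + sampled ROIs."""

    cube: Datacube
    truth: ClassMap
    rois: ROISet
    params: SceneParams
    endmembers: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = float("nan")
    meta: dict[str, Any] = field(default_factory=dict)


def species_presets() -> dict[str, SceneParams]:
    """Parameter bundles mimicking the three graminoid root morphologies:
    fibrous/highly branched (grasses) vs thick/unbranched (the sedge).
    No claim of biological fidelity — they vary geometry, not spectra."""
    base = SceneParams()
    return {
        "fibrous_branched": replace(base, n_roots=4, branch_prob=0.06,
                                    root_dilation_px=1),
        "fibrous_moderate": replace(base, n_roots=3, branch_prob=0.03,
                                    root_dilation_px=2),
        "thick_unbranched": replace(base, n_roots=2, branch_prob=0.0,
                                    root_dilation_px=4),
    }


def endmember_spectra(
    params: SceneParams,
    alpha: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], float]:
    """Class endmembers on the wavelength grid, plus the mixing fraction used.

    soil: low, gently increasing; root: brighter with a sigmoidal red-edge
    rise to a NIR plateau (mean root reflectance exceeds mean soil by
    construction); interface: alpha*root + (1-alpha)*soil with alpha drawn
    from the configured range when not given.
    """
    wl = params.wavelengths.values_nm
    lo, hi = params.wavelength_range_nm
    soil = params.soil_base + params.soil_slope * (wl - lo) / (hi - lo)
    root = params.root_base + params.nir_amplitude / (
        1.0 + np.exp(-(wl - params.red_edge_center_nm) / params.red_edge_width_nm)
    )
    if alpha is None:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        a0, a1 = params.interface_alpha_range
        alpha = float(rng.uniform(a0, a1))
    if not 0 <= alpha <= 1:
        raise ValueError("mixing fraction must lie in [0, 1]")
    interface = alpha * root + (1.0 - alpha) * soil
    return {"soil": soil, "interface": interface, "root": root}, alpha


def _walk(
    start: tuple[int, int],
    params: SceneParams,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """One root strand: downward-biased walk that never moves up and keeps a
    persistent horizontal direction between down-steps (so it never revisits
    a pixel)."""
    h, w = params.height, params.width
    r, c = start
    path = [(r, c)]
    direction = int(rng.choice((-1, 1)))
    max_steps = 4 * (h + w)
    for _ in range(max_steps):
        if r >= h - 1:
            break
        if rng.random() < params.step_bias:
            r += 1
            c = int(np.clip(c + int(rng.integers(-1, 2)), 0, w - 1))
            direction = int(rng.choice((-1, 1)))
        else:
            nxt = c + direction
            if not 0 <= nxt < w:
                direction = -direction
                r += 1  # bounce off the wall downward instead of backtracking
                nxt = c
            c = int(np.clip(nxt, 0, w - 1))
        if path[-1] != (r, c):
            path.append((r, c))
    return path


def draw_root_mask(
    params: SceneParams,
    rng: np.random.Generator | None = None,
    return_paths: bool = False,
):
    """Binary root mask: biased random walks from the top edge with
    branching, dilated to ``root_dilation_px``. Deterministic per seed."""
    if params.n_roots < 1:
        raise ValueError("need at least one root strand")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    mask = np.zeros((h, w), dtype=bool)
    paths: list[list[tuple[int, int]]] = []

    starts: list[tuple[int, int]] = [
        (0, int(rng.integers(w))) for _ in range(params.n_roots)
    ]
    budget = 4 * params.n_roots  # cap total strands incl. branches
    while starts and len(paths) < budget:
        path = _walk(starts.pop(0), params, rng)
        paths.append(path)
        for r, c in path[1:]:
            if rng.random() < params.branch_prob and len(starts) < budget:
                starts.append((r, c))
        for r, c in path:
            mask[r, c] = True

    if params.root_dilation_px > 0:
        mask = _binary_dilate(mask, params.root_dilation_px)
    if return_paths:
        return mask, paths
    return mask


def make_scene(params: SceneParams) -> SyntheticScene:
    """Render a full scene: truth map, datacube, and sampled ROIs.

    Truth: root strands -> class 3, a ``halo_radius_px`` morphological halo
    around them -> class 2 (interface), remainder -> class 1 (soil). The cube
    is per-pixel class endmember x (1 + eps_m) + eps_a with independent
    Gaussian noise per pixel and band. Planted overexposed pixels get one
    random band pushed above reflectance 1 and are unlabeled in truth.
    """
    rng = np.random.default_rng(params.seed)
    h, w, b = params.height, params.width, params.bands

    root = draw_root_mask(params, rng)
    halo = _binary_dilate(root, params.halo_radius_px) if params.halo_radius_px else root
    labels = np.ones((h, w), dtype=np.uint8) * CLASS_IDS["soil"]
    labels[halo & ~root] = CLASS_IDS["interface"]
    labels[root] = CLASS_IDS["root"]

    endmembers, alpha = endmember_spectra(params, rng=rng)
    lut = np.zeros((4, b))
    for name in CLASS_NAMES:
        lut[CLASS_IDS[name]] = endmembers[name]
    data = lut[labels]

    if params.sigma_multiplicative > 0:
        data = data * (1.0 + rng.normal(0.0, params.sigma_multiplicative, data.shape))
    if params.sigma_additive > 0:
        data = data + rng.normal(0.0, params.sigma_additive, data.shape)

    truth = labels.copy()
    n_over = int(round(params.overexposure_fraction * h * w))
    if n_over:
        flat = rng.choice(h * w, size=n_over, replace=False)
        bands_hit = rng.integers(b, size=n_over)
        rr, cc = np.unravel_index(flat, (h, w))
        data[rr, cc, bands_hit] = 1.0 + rng.uniform(0.1, 0.5, size=n_over)
        truth[rr, cc] = 0  # planted defects are the only unlabeled truth

    cube = Datacube(
        data,
        params.wavelengths,
        meta={
            "synthetic": True,
            "seed": params.seed,
            "width_mm": params.physical_width_mm,
            "height_mm": params.physical_height_mm,
        },
    )
    truth_map = ClassMap(truth, provenance={"classifier": "ground_truth",
                                            "seed": params.seed})
    rois = _sample_rois(truth, params, rng)
    return SyntheticScene(
        cube=cube,
        truth=truth_map,
        rois=rois,
        params=params,
        endmembers=endmembers,
        alpha=alpha,
        meta={"n_overexposed_planted": n_over},
    )


def absorption_signal(
    x: np.ndarray,
    centers: tuple[float, ...] = (15.0, 45.0, 75.0, 105.0, 135.0),
    width_bands: float = 3.0,
    depth: float = 0.08,
    base: float = 0.3,
    slope: float = 0.002,
) -> np.ndarray:
    """Smooth root-like spectrum with Gaussian absorption dips (band units).

    A linear baseline minus narrow Gaussian features; the analytic second
    derivative has a peak at each feature center and troughs at the
    +/- sqrt(3)*width inflection shoulders, which is what second-derivative
    band selection is meant to find.
    """
    x = np.asarray(x, dtype=float)
    dips = sum(
        depth * np.exp(-((x - c) ** 2) / (2.0 * width_bands**2))
        for c in centers
    )
    return base + slope * x - dips


def root_spectra_with_features(
    n_spectra: int = 4,
    bands: int = 150,
    noise_sd: float = 0.002,
    seed: int = 0,
    **signal_kwargs: Any,
) -> dict[str, np.ndarray]:
    """A small set of noisy root spectra sharing the same planted features."""
    rng = np.random.default_rng(seed)
    x = np.arange(bands, dtype=float)
    clean = absorption_signal(x, **signal_kwargs)
    return {
        f"im{k}": clean + rng.normal(0.0, noise_sd, bands)
        for k in range(n_spectra)
    }


def _sample_rois(
    truth: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> ROISet:
    """Draw >= 100 pixels per class from correctly-pure truth regions."""
    regions: dict[str, list[tuple[int, int]]] = {}
    for name in CLASS_NAMES:
        coords = np.argwhere(truth == CLASS_IDS[name])
        if coords.shape[0] < 100:
            raise ValueError(
                f"scene too small: class {name!r} has {coords.shape[0]} "
                "pixels, ROI contract needs >= 100"
            )
        take = min(params.roi_pixels, coords.shape[0])
        chosen = coords[rng.choice(coords.shape[0], size=take, replace=False)]
        regions[name] = [tuple(map(int, rc)) for rc in chosen]
    return ROISet(regions, image_shape=(params.height, params.width))
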