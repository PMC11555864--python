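"""Three-class pre-classification of rhizobox datacubes.

Two routes produce the initial soil / root-soil-interface / root labelling
that the downstream label-transfer models are trained on:

* supervised Spectral Angle Mapper (SAM) against per-class mean spectra of
  user-drawn ROIs, with a 10 degree default angle threshold, and
* unsupervised K-Means (Lloyd's algorithm, Euclidean distance over full
  spectra, k=3, max 20 iterations), whose clusters are then named by minimum
  spectral angle to the ROI references.

Labels follow a fixed dictionary: 0 = unlabeled, 1 = soil, 2 = interface,
3 = root. SAM may leave pixels unlabeled (angle above threshold); K-Means
labels every usable pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .cube_io import Datacube

__all__ = [
    "CLASS_NAMES",
    "CLASS_IDS",
    "PALETTE",
    "ROISet",
    "ClassMap",
    "ReferenceSpectra",
    "spectral_angle",
    "roi_mean_spectra",
    "sam_classify",
    "kmeans_classify",
    "map_clusters_to_classes",
    "class_mean_spectra",
]

# fixed class dictionary; order matters for tie-breaking
CLASS_NAMES = ("soil", "interface", "root")
CLASS_IDS: dict[str, int] = {"soil": 1, "interface": 2, "root": 3}
UNLABELED = 0
MIN_ROI_PIXELS = 100

# unlabeled=black, soil=brown, interface=yellow, root=white
PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (139, 69, 19),
    2: (255, 215, 0),
    3: (255, 255, 255),
}


@dataclass
class ROISet:
    """Manually selected per-class pixel coordinate lists.

    Each region should contain at least 100 pixels (a warning, not an error:
    the minimum is a study convention, not an algorithmic requirement);
    regions must be disjoint and inside the image bounds.
    """

    regions: dict[str, list[tuple[int, int]]]
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.regions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI classes: {sorted(unknown)}")
        seen: set[tuple[int, int]] = set()
        for name in CLASS_NAMES:
            coords = [tuple(map(int, rc)) for rc in self.regions.get(name, [])]
            self.regions[name] = coords  # type: ignore[index]
            if 0 < len(coords) < MIN_ROI_PIXELS:
                warnings.warn(
                    f"ROI {name!r} has only {len(coords)} pixels "
                    f"(< {MIN_ROI_PIXELS})",
                    stacklevel=2,
                )
            overlap = seen.intersection(coords)
            if overlap:
                raise ValueError(f"ROIs overlap at {sorted(overlap)[:3]} ...")
            seen.update(coords)
            if self.image_shape is not None:
                h, w = self.image_shape
                for r, c in coords:
                    if not (0 <= r < h and 0 <= c < w):
                        raise ValueError(f"ROI pixel ({r}, {c}) out of bounds")

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "ROISet":
        """Build from an indexed mask image (0 background, 1/2/3 classes)."""
        mask = np.asarray(mask)
        regions = {
            name: [tuple(rc) for rc in np.argwhere(mask == CLASS_IDS[name])]
            for name in CLASS_NAMES
        }
        return cls(regions, image_shape=mask.shape)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ROISet":
        """Read (class,row,col) rows."""
        frame = pd.read_csv(path)
        regions: dict[str, list[tuple[int, int]]] = {n: [] for n in CLASS_NAMES}
        for row in frame.itertuples(index=False):
            regions[str(row[0])].append((int(row[1]), int(row[2])))
        return cls(regions)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (name, r, c)
            for name in CLASS_NAMES
            for r, c in self.regions.get(name, [])
        ]
        pd.DataFrame(rows, columns=["class", "row", "col"]).to_csv(
            path, index=False
        )


@dataclass
class ClassMap:
    """Per-pixel label image over {0 unlabeled, 1 soil, 2 interface, 3 root}."""

    labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.isin(labels, (0, 1, 2, 3)).all():
            raise ValueError("labels restricted to {0, 1, 2, 3}")
        self.labels = labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        out = {label: 0 for label in PALETTE}
        out.update(dict(zip(values.tolist(), counts.tolist())))
        return out

    def to_png(self, path: str | Path) -> None:
        """Write as indexed PNG with the fixed class palette."""
        img = Image.fromarray(self.labels, mode="P")
        palette = [0] * 768
        for label, rgb in PALETTE.items():
            palette[3 * label : 3 * label + 3] = rgb
        img.putpalette(palette)
        img.save(path, format="PNG")

    @classmethod
    def from_png(cls, path: str | Path) -> "ClassMap":
        img = Image.open(path)
        return cls(np.asarray(img, dtype=np.uint8))


@dataclass
class ReferenceSpectra:
    """Per-class mean reflectance vectors plus the pixel counts behind them."""

    spectra: dict[str, np.ndarray]
    pixel_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = {k: np.asarray(v, dtype=float) for k, v in self.spectra.items()}
        lengths = {v.size for v in self.spectra.values()}
        if len(lengths) > 1:
            raise ValueError("reference spectra must share one band axis")

    def matrix(self, order: Sequence[str] = CLASS_NAMES) -> np.ndarray:
        return np.stack([self.spectra[name] for name in order])


# ---------------------------------------------------------------------------

def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two spectra, in [0, 180].

    Scale-invariant under positive scaling of either argument; raises on a
    zero-norm input (callers treat such pixels as unlabeled).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral angle undefined for a zero-norm spectrum")
    cosine = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _angles_to_refs(pixels: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """(N, B) x (K, B) -> (N, K) angles in degrees; zero-norm pixels -> NaN."""
    pnorm = np.linalg.norm(pixels, axis=1, keepdims=True)
    rnorm = np.linalg.norm(refs, axis=1, keepdims=True)
    if np.any(rnorm == 0):
        raise ValueError("reference spectrum with zero norm")
    with np.errstate(divide="ignore", invalid="ignore"):
        cosine = (pixels @ refs.T) / (pnorm * rnorm.T)
    angles = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    angles[pnorm[:, 0] == 0] = np.nan
    return angles


def roi_mean_spectra(cube: Datacube, rois: ROISet) -> ReferenceSpectra:
    """Per-class arithmetic mean spectrum over ROI pixels (masked excluded)."""
    spectra: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for name in CLASS_NAMES:
        coords = rois.regions.get(name, [])
        usable = [
            (r, c) for r, c in coords if cube.pixel_mask[r, c]
        ]
        if not usable:
            raise ValueError(f"ROI {name!r} has no usable pixels")
        rows, cols = zip(*usable)
        spectra[name] = cube.data[list(rows), list(cols)].mean(axis=0)
        counts[name] = len(usable)
    return ReferenceSpectra(spectra, counts)


def sam_classify(
    cube: Datacube,
    refs: ReferenceSpectra,
    threshold_deg: float = 10.0,
) -> ClassMap:
    """Spectral Angle Mapper: label each pixel by its nearest reference.

    A pixel gets the class of minimum angle when that angle is <= the
    threshold, otherwise stays unlabeled; masked and zero-norm pixels are
    unlabeled. Ties break toward the fixed class order soil < interface < root.
    """
    missing = set(CLASS_NAMES) - set(refs.spectra)
    if missing:
        raise ValueError(f"reference spectra missing classes: {sorted(missing)}")
    h, w, _ = cube.shape
    pixels = cube.spectra_2d()
    angles = _angles_to_refs(pixels, refs.matrix())

    labels = np.zeros(h * w, dtype=np.uint8)
    valid = ~np.isnan(angles).any(axis=1)
    # argmin returns the first minimum -> ties break to the lower class id
    best = np.argmin(angles[valid], axis=1)
    within = np.take_along_axis(
        angles[valid], best[:, None], axis=1
    )[:, 0] <= threshold_deg
    assigned = np.zeros(valid.sum(), dtype=np.uint8)
    assigned[within] = best[within].astype(np.uint8) + 1
    labels[valid] = assigned
    labels = labels.reshape(h, w)
    labels[~cube.pixel_mask] = UNLABELED
    return ClassMap(
        labels,
        provenance={"classifier": "sam", "threshold_deg": threshold_deg},
    )


def _farthest_point_init(
    pixels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-point seeding: random first centre, then maximal
    nearest-centre distance (deterministic given the generator state)."""
    n = pixels.shape[0]
    centers = [int(rng.integers(n))]
    dist = np.linalg.norm(pixels - pixels[centers[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pixels - pixels[nxt], axis=1))
    return pixels[centers].copy()


def kmeans_classify(
    cube: Datacube,
    k: int = 3,
    max_iter: int = 20,
    seed: int = 0,
) -> tuple[ClassMap, np.ndarray]:
    """Lloyd's K-Means over full pixel spectra (Euclidean distance).

    Every usable pixel is assigned a cluster; iteration stops at convergence
    (no assignment change) or ``max_iter``. Deterministic for a fixed seed.
    Returns the cluster map (labels 1..k in cluster order — use
    :func:`map_clusters_to_classes` to name them) and the k centroids.
    """
    h, w, b = cube.shape
    flat_mask = cube.pixel_mask.ravel()
    pixels = cube.spectra_2d()[flat_mask]
    if pixels.shape[0] < k:
        raise ValueError("fewer usable pixels than clusters")
    if np.unique(pixels, axis=0).shape[0] < k:
        raise ValueError("fewer distinct pixels than clusters")

    rng = np.random.default_rng(seed)
    centroids = _farthest_point_init(pixels, k, rng)
    assignment = np.full(pixels.shape[0], -1)
    for _ in range(max_iter):
        d2 = (
            (pixels**2).sum(axis=1, keepdims=True)
            - 2.0 * pixels @ centroids.T
            + (centroids**2).sum(axis=1)
        )
        new_assignment = np.argmin(d2, axis=1)
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for j in range(k):
            members = pixels[assignment == j]
            if members.shape[0]:  # empty cluster keeps its centroid
                centroids[j] = members.mean(axis=0)

    labels = np.zeros(h * w, dtype=np.uint8)
    labels[flat_mask] = assignment.astype(np.uint8) + 1
    return (
        ClassMap(
            labels.reshape(h, w),
            provenance={
                "classifier": "kmeans",
                "k": k,
                "max_iter": max_iter,
                "seed": seed,
            },
        ),
        centroids,
    )


def map_clusters_to_classes(
    centroids: np.ndarray,
    refs: ReferenceSpectra | None = None,
) -> dict[int, int]:
    """Name K-Means clusters: cluster label (1..k) -> semantic class id.

    With references, each centroid takes the class of minimum spectral angle.
    Without, a documented heuristic orders clusters by mean reflectance
    (soil < interface < root), which requires k = 3.
    """
    centroids = np.asarray(centroids, dtype=float)
    if refs is not None:
        angles = _angles_to_refs(centroids, refs.matrix())
        return {
            j + 1: int(np.argmin(angles[j])) + 1
            for j in range(centroids.shape[0])
        }
    if centroids.shape[0] != len(CLASS_NAMES):
        raise ValueError("reflectance-ordering heuristic requires k = 3")
    order = np.argsort(centroids.mean(axis=1), kind="stable")
    return {int(cluster) + 1: rank + 1 for rank, cluster in enumerate(order)}


def relabel(cmap: ClassMap, mapping: Mapping[int, int]) -> ClassMap:
    """Apply a cluster -> class mapping to a cluster map (0 stays 0)."""
    lut = np.zeros(256, dtype=np.uint8)
    for src, dst in mapping.items():
        lut[src] = dst
    provenance = dict(cmap.provenance)
    provenance["cluster_to_class"] = {int(k): int(v) for k, v in mapping.items()}
    return ClassMap(lut[cmap.labels], provenance)


def class_mean_spectra(
    cube: Datacube,
    cmap: ClassMap,
    image_id: str = "image",
) -> pd.DataFrame:
    """Long-format table of per-class per-band mean reflectance.

    One row per (image, class, band); classes with zero member pixels are
    omitted with a warning, unlabeled pixels are never included.
    """
    if cmap.shape != cube.shape[:2]:
        raise ValueError("class map not aligned to cube")
    rows: list[pd.DataFrame] = []
    for name in CLASS_NAMES:
        member = (cmap.labels == CLASS_IDS[name]) & cube.pixel_mask
        if not member.any():
            warnings.warn(f"class {name!r} has no pixels; omitted", stacklevel=2)
            continue
        mean = cube.data[member].mean(axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "image_id": image_id,
                    "class": name,
                    "wavelength_nm": cube.wavelengths.values_nm,
                    "mean_reflectance": mean,
                }
            )
        )
    if not rows:
        raise ValueError("no labeled pixels in class map")
    return pd.concat(rows, ignore_index=True)
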