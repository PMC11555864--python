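"""Surface-biomass estimation from class maps.

Class pixel counts are converted to percentages of the whole image and then
to physical areas using the image's physical dimensions (e.g. 115 x 155 mm
for the whole-rhizobox configuration). These are surface approximations:
they capture only the visible face of the root system at the observation
panel, not biomass hidden in the rhizobox depth, and were never calibrated
against destructively measured biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .classify import CLASS_IDS, CLASS_NAMES, ClassMap

__all__ = [
    "PhysicalDims",
    "BiomassEstimate",
    "class_percentages",
    "estimate_area",
    "timeseries",
]

LABEL_NAMES = {0: "unlabeled", 1: "soil", 2: "interface", 3: "root"}


@dataclass(frozen=True)
class PhysicalDims:
    """Physical image extent in millimetres."""

    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("physical dimensions must be positive")

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm


@dataclass
class BiomassEstimate:
    """Per-class pixel counts, percentages, and areas for one image."""

    counts: dict[str, int]
    percentages: dict[str, float]
    areas_mm2: dict[str, float]
    total_area_mm2: float
    image_id: str = ""
    timestamp_days: float | None = None
    replicate: str = ""
    species: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": self.image_id,
                "timestamp_days": self.timestamp_days,
                "species": self.species,
                "replicate": self.replicate,
                "class": name,
                "pixel_count": self.counts[name],
                "percent": self.percentages[name],
                "area_mm2": self.areas_mm2[name],
            }
            for name in self.counts
        ]
        return pd.DataFrame(rows)


def class_percentages(cmap: ClassMap) -> dict[str, float]:
    """Percent of ALL pixels per class (unlabeled kept in the denominator).

    The unlabeled share is reported explicitly rather than silently
    redistributed; percentages sum to 100.
    """
    total = cmap.labels.size
    counts = cmap.class_counts()
    return {
        LABEL_NAMES[label]: 100.0 * counts.get(label, 0) / total
        for label in sorted(LABEL_NAMES)
    }


def estimate_area(
    cmap: ClassMap,
    dims: PhysicalDims,
    image_id: str = "",
    timestamp_days: float | None = None,
    replicate: str = "",
    species: str = "",
) -> BiomassEstimate:
    """Per-class surface area: class fraction x physical width x height.

    Resolution-invariant by construction (percent-based) and conservative:
    class areas sum exactly to the physical image area.
    """
    counts_by_label = cmap.class_counts()
    percentages = class_percentages(cmap)
    counts = {
        LABEL_NAMES[label]: counts_by_label.get(label, 0)
        for label in sorted(LABEL_NAMES)
    }
    areas = {
        name: pct / 100.0 * dims.area_mm2 for name, pct in percentages.items()
    }
    return BiomassEstimate(
        counts=counts,
        percentages=percentages,
        areas_mm2=areas,
        total_area_mm2=dims.area_mm2,
        image_id=image_id,
        timestamp_days=timestamp_days,
        replicate=replicate,
        species=species,
        meta={"width_mm": dims.width_mm, "height_mm": dims.height_mm},
    )


def timeseries(estimates: Sequence[BiomassEstimate]) -> pd.DataFrame:
    """Mean +/- standard error of class areas over biological replicates.

    Groups by (species, class, timestamp); SE = sample SD / sqrt(n), reported
    as 0 and flagged (``single_replicate``) when only one replicate exists.
    """
    if not estimates:
        raise ValueError("no estimates to summarise")
    long = pd.concat([e.to_frame() for e in estimates], ignore_index=True)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    grouped = (
        long.groupby(["species", "class", "timestamp_days"], dropna=False)
        .agg(
            mean_area_mm2=("area_mm2", "mean"),
            se_area_mm2=("area_mm2", _se),
            n_replicates=("area_mm2", "size"),
        )
        .reset_index()
    )
    grouped["single_replicate"] = grouped["n_replicates"] == 1
    return grouped
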