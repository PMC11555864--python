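"""End-to-end pipeline driver: correct -> mask -> pre-classify -> select ->
train -> predict -> evaluate -> biomass, with a hashed artifact manifest.

The driver consumes a structured config (YAML mapping or dict), materialises
every default into an echoed effective config, runs the stages in order, and
writes each artifact plus a ``manifest.json`` listing content hashes — a
rerun with identical config and inputs reproduces identical hashes. All
randomness flows from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import band_select, biomass, classify, cube_io, model, synthgen

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_config",
    "label_transfer_benchmark",
]


@dataclass
class PipelineConfig:
    """Fully materialised stage parameters; unknown keys are rejected."""

    output_dir: str = "rhizospec_out"
    seed: int = 0
    # input: either a synthetic scene spec or paths to an ENVI cube + ROI csv
    simulate: dict[str, Any] = field(default_factory=dict)
    cube_path: str | None = None
    roi_path: str | None = None
    # stage parameters
    sam_threshold_deg: float = 10.0
    kmeans_k: int = 3
    kmeans_max_iter: int = 20
    savgol_window: int = 21
    savgol_polyorder: int = 3
    min_prominence_frac: float = 0.05
    min_separation_bands: int = 3
    crop_window: list[int] | None = None  # [row0, col0, height, width]
    train_fraction: float = 0.8
    split_seed: int = 0
    classifier: str = "rf"
    rf_estimators: int = 50
    svm_c: float = 1.0
    width_mm: float = 115.0
    height_mm: float = 155.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.savgol_polyorder < 2 or self.savgol_polyorder >= self.savgol_window:
            raise ValueError("polyorder must satisfy 2 <= polyorder < window")
        if self.classifier not in {"rf", "svm"}:
            raise ValueError("classifier must be 'rf' or 'svm'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.simulate and self.cube_path is None:
            raise ValueError("config needs either 'simulate' or 'cube_path'")

    def effective(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(source: str | Path | dict[str, Any]) -> PipelineConfig:
    """Build a config from a YAML file or mapping; unknown keys are errors."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def label_transfer_benchmark(
    seed: int,
    params: "synthgen.SceneParams | None" = None,
) -> dict[str, Any]:
    """Run both label-transfer routes on one synthetic scene.

    Renders a scene, pre-classifies it with SAM and with named K-Means,
    selects bands from each route's root-class mean spectrum, trains a
    Random Forest on each label set (80/20 split), predicts the whole image,
    and scores both predictions against the scene's ground truth. Returns
    the macro F1 of each route plus the selected band counts.
    """
    base = params or synthgen.SceneParams()
    scene = synthgen.make_scene(dataclasses.replace(base, seed=seed))
    cube = cube_io.mask_overexposed(scene.cube)

    refs = classify.roi_mean_spectra(cube, scene.rois)
    sam_map = classify.sam_classify(cube, refs)
    km_map, centroids = classify.kmeans_classify(cube, seed=seed)
    km_map = classify.relabel(
        km_map, classify.map_clusters_to_classes(centroids, refs)
    )

    out: dict[str, Any] = {"seed": seed}
    for source, cmap in (("sam", sam_map), ("kmeans", km_map)):
        table = classify.class_mean_spectra(cube, cmap, image_id=source)
        root = (
            table[table["class"] == "root"]
            .sort_values("wavelength_nm")["mean_reflectance"]
            .to_numpy()
        )
        dset = band_select.DerivativeSet.from_spectra({source: root})
        selection = band_select.select_bands(
            band_select.average_d2(dset),
            cube.wavelengths.values_nm,
            source=source,
        )
        pixels = model.assemble_training(
            [(cube, cmap)], [None], selection, label_source=source  # type: ignore[arg-type]
        )
        train_tab, _ = model.split(pixels, model.SplitSpec())
        clf = model.train(train_tab, "rf", selection, seed=seed)
        pred = model.predict_image(clf, cube)
        report = model.evaluate(pred, scene.truth)
        out[f"{source}_macro_f1"] = report.macro_f1
        out[f"{source}_n_bands"] = len(selection)
    return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order and return the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stages_ok: list[str] = []

    def emit(path: Path) -> None:
        artifacts.append(path)

    # --- input ------------------------------------------------------------
    if config.simulate:
        params = synthgen.SceneParams(**{**config.simulate, "seed": config.seed})
        scene = synthgen.make_scene(params)
        cube, rois, truth = scene.cube, scene.rois, scene.truth
        hdr = cube_io.write_envi(cube, out / "scene")
        emit(hdr)
        emit(hdr.with_suffix(".img"))
        emit(hdr.with_suffix(".json"))
        truth.to_png(out / "truth.png")
        emit(out / "truth.png")
        rois.to_csv(out / "rois.csv")
        emit(out / "rois.csv")
    else:
        cube = cube_io.read_envi(config.cube_path)
        if config.roi_path is None:
            raise ValueError("cube input requires an ROI file")
        rois = classify.ROISet.from_csv(config.roi_path)
        truth = None
    stages_ok.append("input")

    # --- hygiene ----------------------------------------------------------
    cube = cube_io.mask_overexposed(cube)
    stages_ok.append("mask_overexposed")

    # --- pre-classification -----------------------------------------------
    refs = classify.roi_mean_spectra(cube, rois)
    sam_map = classify.sam_classify(cube, refs, config.sam_threshold_deg)
    sam_map.to_png(out / "sam.png")
    emit(out / "sam.png")
    stages_ok.append("sam")

    km_map, centroids = classify.kmeans_classify(
        cube, config.kmeans_k, config.kmeans_max_iter, seed=config.seed
    )
    mapping = classify.map_clusters_to_classes(centroids, refs)
    km_map = classify.relabel(km_map, mapping)
    km_map.to_png(out / "kmeans.png")
    emit(out / "kmeans.png")
    stages_ok.append("kmeans")

    spectra_table = classify.class_mean_spectra(cube, sam_map, image_id="sam")
    spectra_table.to_csv(out / "class_spectra.csv", index=False)
    emit(out / "class_spectra.csv")
    stages_ok.append("spectra")

    # --- band selection (root-class spectra only) -------------------------
    root_mean = (
        spectra_table.query("`class` == 'root'")
        .sort_values("wavelength_nm")["mean_reflectance"]
        .to_numpy()
    )
    dset = band_select.DerivativeSet.from_spectra(
        {"sam": root_mean}, config.savgol_window, config.savgol_polyorder
    )
    selection = band_select.select_bands(
        band_select.average_d2(dset),
        cube.wavelengths.values_nm,
        config.min_prominence_frac,
        config.min_separation_bands,
        source="sam",
    )
    selection.to_frame().to_csv(out / "band_selection.csv", index=False)
    emit(out / "band_selection.csv")
    stages_ok.append("select_bands")

    # --- train / predict / evaluate ---------------------------------------
    window = tuple(config.crop_window) if config.crop_window else None
    table = model.assemble_training(
        [(cube, sam_map)], [window], selection, label_source="sam"
    )
    train_tab, test_tab = model.split(
        table, model.SplitSpec(config.train_fraction, config.split_seed)
    )
    clf = model.train(
        train_tab,
        kind=config.classifier,  # type: ignore[arg-type]
        selection=selection,
        n_estimators=config.rf_estimators,
        seed=config.seed,
        svm_c=config.svm_c,
    )
    stages_ok.append("train")

    pred = model.predict_image(clf, cube)
    pred.to_png(out / "predicted.png")
    emit(out / "predicted.png")
    stages_ok.append("predict")

    reference = truth if truth is not None else sam_map
    report = model.evaluate(pred, reference)
    (out / "metrics.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    emit(out / "metrics.json")
    report.to_table().to_csv(out / "metrics.csv", index=False)
    emit(out / "metrics.csv")
    stages_ok.append("evaluate")

    # --- biomass -----------------------------------------------------------
    dims = biomass.PhysicalDims(config.width_mm, config.height_mm)
    estimate = biomass.estimate_area(pred, dims, image_id="predicted")
    estimate.to_frame().to_csv(out / "biomass.csv", index=False)
    emit(out / "biomass.csv")
    stages_ok.append("biomass")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "effective_config": config.effective(),
        "stages": stages_ok,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
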