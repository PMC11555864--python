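"""Label-transfer machine learning over selected bands.

A pre-classification (SAM or K-Means) supplies pixel labels inside 300 x 300
crops at the root-soil interface; those labeled pixels, restricted to the
selected wavelengths, train a Random Forest (50 trees) or linear SVM that
then predicts whole images. Evaluation follows standard segmentation
practice: per-class precision/recall/F1 with supports, a macro-average F1
over the three semantic classes (never over the unlabeled pseudo-class), and
the full confusion matrix. A 2-component PLS on per-class mean spectra
summarises how classes separate across species and imaging configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .band_select import BandSelection
from .classify import CLASS_IDS, CLASS_NAMES, ClassMap
from .cube_io import Datacube

__all__ = [
    "PixelTable",
    "SplitSpec",
    "TrainedClassifier",
    "MetricsReport",
    "LatentScores",
    "assemble_training",
    "split",
    "train",
    "predict_image",
    "evaluate",
    "f1_from_precision_recall",
    "macro_f1",
    "pls_scores",
]

SEMANTIC_IDS = tuple(CLASS_IDS[name] for name in CLASS_NAMES)  # (1, 2, 3)


@dataclass
class PixelTable:
    """Labeled pixels as rows, selected-band reflectances as columns.

    ``frame`` holds one float column per selected wavelength (ordered by
    wavelength, named ``nm_<wavelength>``) plus an integer ``label`` column;
    unlabeled and masked pixels never appear.
    """

    frame: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise ValueError("pixel table needs a 'label' column")
        if (self.frame["label"] == 0).any():
            raise ValueError("pixel table must not contain unlabeled rows")

    @property
    def band_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "label"]

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.frame[self.band_columns].to_numpy(dtype=float),
            self.frame["label"].to_numpy(dtype=int),
        )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SplitSpec:
    """Uniform random train/test split (no stratification)."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class TrainedClassifier:
    """A fitted label-transfer model bound to one band selection."""

    kind: Literal["rf", "svm"]
    estimator: Any
    selection: BandSelection
    classes: tuple[int, ...]
    hyperparams: dict[str, Any] = field(default_factory=dict)
    label_source: str = ""


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/support, macro F1, confusion matrix."""

    per_class: pd.DataFrame  # index: class name; columns: precision/recall/f1/support
    macro_f1: float
    confusion: pd.DataFrame  # truth rows x predicted columns, labeled
    n_evaluated: int

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "per_class": self.per_class.round(6).to_dict(orient="index"),
            "macro_f1": round(self.macro_f1, 6),
            "confusion": {
                "labels_truth": list(self.confusion.index),
                "labels_pred": list(self.confusion.columns),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "n_evaluated": self.n_evaluated,
        }

    def to_table(self) -> pd.DataFrame:
        """Flat CSV form: class, precision, recall, f1, support."""
        out = self.per_class.reset_index(names="class")
        macro = pd.DataFrame(
            [
                {
                    "class": "macro_avg",
                    "precision": self.per_class["precision"].mean(),
                    "recall": self.per_class["recall"].mean(),
                    "f1": self.macro_f1,
                    "support": int(self.per_class["support"].sum()),
                }
            ]
        )
        return pd.concat([out, macro], ignore_index=True)


@dataclass
class LatentScores:
    """PLS sample scores and band loadings with their grouping labels."""

    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_bands, n_components)
    groups: tuple[str, ...]
    n_components: int


# ---------------------------------------------------------------------------

def assemble_training(
    pairs: Sequence[tuple[Datacube, ClassMap]],
    crop_windows: Sequence[tuple[int, int, int, int] | None],
    selection: BandSelection,
    label_source: Literal["sam", "kmeans"] = "sam",
    image_ids: Sequence[str] | None = None,
) -> PixelTable:
    """Concatenate labeled pixels from cropped (cube, class map) pairs.

    Each crop window is (row0, col0, height, width) or None for the whole
    image; unlabeled and masked pixels are dropped (the SAM route leaves
    above-threshold pixels unlabeled, and those rows are excluded). Band
    columns are ordered by wavelength.
    """
    from .cube_io import crop as crop_cube  # local to avoid cycle at import

    if len(pairs) != len(crop_windows):
        raise ValueError("one crop window (or None) per image pair required")
    if image_ids is None:
        image_ids = [f"image_{i}" for i in range(len(pairs))]

    columns = [f"nm_{wl:.1f}" for wl in selection.wavelengths_nm]
    frames: list[pd.DataFrame] = []
    for (cube, cmap), window, image_id in zip(pairs, crop_windows, image_ids):
        if cmap.shape != cube.shape[:2]:
            raise ValueError(f"class map misaligned for {image_id}")
        labels = cmap.labels
        if window is not None:
            r0, c0, hh, ww = window
            cube = crop_cube(cube, r0, c0, hh, ww)
            labels = labels[r0 : r0 + hh, c0 : c0 + ww]
        if label_source == "sam":
            present = {int(v) for v in np.unique(labels)} & set(SEMANTIC_IDS)
            if present != set(SEMANTIC_IDS):
                warnings.warn(
                    f"crop of {image_id} lacks some classes: has {sorted(present)}",
                    stacklevel=2,
                )
        keep = (labels > 0) & cube.pixel_mask
        if not keep.any():
            continue
        features = cube.data[keep][:, selection.indices]
        frame = pd.DataFrame(features, columns=columns)
        frame["label"] = labels[keep].astype(int)
        frames.append(frame)

    if not frames:
        raise ValueError("no labeled pixels remain after filtering")
    table = pd.concat(frames, ignore_index=True)
    return PixelTable(
        table,
        provenance={
            "image_ids": list(image_ids),
            "crop_windows": [list(w) if w else None for w in crop_windows],
            "label_source": label_source,
            "band_indices": selection.indices.tolist(),
        },
    )


def split(table: PixelTable, spec: SplitSpec = SplitSpec()) -> tuple[PixelTable, PixelTable]:
    """Deterministic uniform row split; |train| = round(train_fraction * n)."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    prov = dict(table.provenance)
    prov["split"] = {"train_fraction": spec.train_fraction, "seed": spec.seed}
    return (
        PixelTable(table.frame.iloc[np.sort(train_idx)].reset_index(drop=True), prov),
        PixelTable(table.frame.iloc[np.sort(test_idx)].reset_index(drop=True), prov),
    )


def train(
    table: PixelTable,
    kind: Literal["rf", "svm"] = "rf",
    selection: BandSelection | None = None,
    n_estimators: int = 50,
    seed: int = 0,
    svm_c: float = 1.0,
) -> TrainedClassifier:
    """Fit the label-transfer classifier (RF, 50 trees, or linear SVM)."""
    X, y = table.xy()
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ValueError("training table holds a single class")
    if kind == "rf":
        est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        hyper = {"n_estimators": n_estimators, "seed": seed}
    elif kind == "svm":
        est = SVC(kernel="linear", C=svm_c, random_state=seed)
        hyper = {"kernel": "linear", "C": svm_c}
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(X, y)
    if selection is None:
        indices = table.provenance.get("band_indices")
        wl = [float(c[3:]) for c in table.band_columns]
        selection = BandSelection(
            np.array(indices if indices is not None else range(len(wl)), dtype=int),
            np.array(wl),
        )
    return TrainedClassifier(
        kind,
        est,
        selection,
        classes,
        hyper,
        label_source=str(table.provenance.get("label_source", "")),
    )


def predict_image(model: TrainedClassifier, cube: Datacube) -> ClassMap:
    """Predict a class for every usable pixel; masked pixels stay unlabeled.

    The cube's wavelength axis must match the model's band selection to
    within one band-center spacing.
    """
    sel = model.selection
    if sel.indices.max(initial=-1) >= cube.n_bands:
        raise ValueError("band selection exceeds cube band count")
    cube_wl = cube.wavelengths.values_nm[sel.indices]
    spacing = float(np.median(np.diff(cube.wavelengths.values_nm)))
    if np.any(np.abs(cube_wl - sel.wavelengths_nm) > spacing):
        raise ValueError("cube wavelengths incompatible with band selection")

    h, w, _ = cube.shape
    flat_mask = cube.pixel_mask.ravel()
    labels = np.zeros(h * w, dtype=np.uint8)
    if flat_mask.any():
        X = cube.spectra_2d()[flat_mask][:, sel.indices]
        labels[flat_mask] = model.estimator.predict(X).astype(np.uint8)
    return ClassMap(
        labels.reshape(h, w),
        provenance={
            "classifier": model.kind,
            "label_source": model.label_source,
            "hyperparams": model.hyperparams,
        },
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_f1(f1_scores: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-class F1-scores."""
    scores = np.asarray(f1_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no F1-scores to average")
    return float(scores.mean())


def evaluate(pred: ClassMap, truth: ClassMap) -> MetricsReport:
    """Score a predicted map against reference labels.

    Pixels whose truth is unlabeled are excluded from the per-class metrics
    (unlabeled reference pixels carry no information and would skew the
    averages) but appear as an extra truth row of the confusion matrix when
    present. Macro F1 averages over the three semantic classes only.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth maps must be aligned")
    t = truth.labels.ravel().astype(int)
    p = pred.labels.ravel().astype(int)
    evaluable = t > 0
    if not evaluable.any():
        raise ValueError("no evaluable pixels (all truth unlabeled)")

    te, pe = t[evaluable], p[evaluable]
    rows = {}
    f1s = []
    for name in CLASS_NAMES:
        cid = CLASS_IDS[name]
        tp = int(np.sum((te == cid) & (pe == cid)))
        fp = int(np.sum((te != cid) & (pe == cid)))
        fn = int(np.sum((te == cid) & (pe != cid)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = f1_from_precision_recall(precision, recall)
        rows[name] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": tp + fn,
        }
        f1s.append(f1)

    truth_labels = sorted({int(v) for v in np.unique(t)})
    pred_labels = sorted({int(v) for v in np.unique(p)} | set(SEMANTIC_IDS))
    confusion = pd.DataFrame(
        0, index=truth_labels, columns=pred_labels, dtype=int
    )
    for ti in truth_labels:
        for pi in pred_labels:
            confusion.loc[ti, pi] = int(np.sum((t == ti) & (p == pi)))

    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class["support"] = per_class["support"].astype(int)
    return MetricsReport(
        per_class=per_class,
        macro_f1=macro_f1(f1s),
        confusion=confusion,
        n_evaluated=int(evaluable.sum()),
    )


def pls_scores(
    spectra: pd.DataFrame,
    groups: Sequence[str],
    n_components: int = 2,
) -> LatentScores:
    """PLS latent scores of class-mean spectra against a one-hot grouping.

    ``spectra`` is samples x bands (one row per class-spectrum observation);
    ``groups`` labels each row (e.g. "root|speciesA"). The response is the
    one-hot group indicator; scores are the X-block latent coordinates and
    loadings the per-band weights. Deterministic.
    """
    X = np.asarray(spectra, dtype=float)
    groups = tuple(str(g) for g in groups)
    if X.ndim != 2 or X.shape[0] != len(groups):
        raise ValueError("spectra rows and group labels must correspond")
    if len(set(groups)) < 2:
        raise ValueError("need at least 2 distinct groups")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant predictor matrix")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])

    levels = sorted(set(groups))
    Y = np.zeros((len(groups), len(levels)))
    for i, g in enumerate(groups):
        Y[i, levels.index(g)] = 1.0

    pls = PLSRegression(
        # run NIPALS essentially to machine precision; cheap at these sizes
        n_components=n_components, scale=False, max_iter=20000, tol=1e-30
    )
    pls.fit(X, Y)
    return LatentScores(
        scores=np.asarray(pls.x_scores_),
        loadings=np.asarray(pls.x_loadings_),
        groups=groups,
        n_components=n_components,
    )
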