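"""End-to-end orchestration: extract -> train -> evaluate.

The feature table produced by :func:`run_extract` carries the 13 geometric
features plus the 32-dimensional raw polar Fourier descriptor per object;
:func:`run_train` fits the descriptor PCA on the training table only (no
leakage into testing), assembles the 21-feature vectors and trains the
21-8-5 network; :func:`run_evaluate` applies the frozen PCA + network to a
test table and reports the confusion matrix.  Identical config + seed give
identical tables, models and reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from algascope import features as ft
from algascope import mlp as nn
from algascope import synth
from algascope.preprocess import load_image
from algascope.segmentation import CannyParams, SegmentedObject, segment_image

log = logging.getLogger("algascope")

GEOM_COLS = ft.FEATURE_NAMES[:13]
DESC_COLS = [f"spectrum_{i:02d}" for i in range(32)]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study defaults."""

    sigma: float = 1.4
    low_threshold: float = 0.1
    high_threshold: float = 0.25
    min_area: int = 50
    overlap_rect: int = 50
    circularity_threshold: float = 0.8
    elongation_threshold: float = 2.5
    n_strips: int = 5
    pca_k: int = 8
    spectrum_size: int = 64
    spectrum_bins: int = 16
    learning_rate: float = 0.05
    momentum: float = 0.05
    max_epochs: int = 400
    validation_fraction: float = 0.10
    patience: int = 10
    unknown_threshold: float = 0.5
    n_train_per_class: int = 40
    n_test_per_class: int = 50
    canvas: tuple[int, int] = (288, 360)
    seed: int = 0

    @property
    def canny(self) -> CannyParams:
        return CannyParams(self.sigma, self.low_threshold, self.high_threshold)

    @property
    def training(self) -> nn.TrainingConfig:
        return nn.TrainingConfig(learning_rate=self.learning_rate,
                                 momentum=self.momentum,
                                 max_epochs=self.max_epochs,
                                 validation_fraction=self.validation_fraction,
                                 seed=self.seed, patience=self.patience)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["canvas"] = tuple(d["canvas"])
        return cls(**d)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        d = dataclasses.asdict(self)
        for key, val in overrides.items():
            if key not in d:
                raise KeyError(f"unknown config key {key!r}")
            cur = d[key]
            d[key] = type(cur)(val) if not isinstance(cur, tuple) else tuple(val)
        d["canvas"] = tuple(d["canvas"])
        return PipelineConfig(**d)


@dataclass
class RunReport:
    """Evaluation summary for one pipeline run."""

    object_counts: dict = field(default_factory=dict)
    predictions: list = field(default_factory=list)
    confusion: dict | None = None
    overall_accuracy: float = float("nan")
    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "object_counts": self.object_counts,
            "predictions": self.predictions,
            "overall_accuracy": self.overall_accuracy,
            "train_rmse": self.train_rmse,
            "val_rmse": self.val_rmse,
            "timings": self.timings,
        }
        if self.confusion is not None:
            payload["confusion_labels"] = self.confusion["labels"]
            payload["confusion_matrix"] = np.asarray(self.confusion["matrix"]).tolist()
            payload["per_class_accuracy"] = self.confusion["per_class_accuracy"]
        Path(path).write_text(json.dumps(payload, indent=1))

    def confusion_frame(self) -> pd.DataFrame:
        labels = self.confusion["labels"]
        return pd.DataFrame(self.confusion["matrix"], index=labels, columns=labels)


# ---------------------------------------------------------------------------
# extraction


def extract_objects(rgb: np.ndarray, config: PipelineConfig = PipelineConfig()
                    ) -> list[tuple[SegmentedObject, np.ndarray, np.ndarray]]:
    """Segment one image and measure each object.

    Returns ``(object, geometry_features_13, raw_descriptor_32)`` triples.
    """
    objects = segment_image(rgb, params=config.canny, min_area=config.min_area,
                            overlap_rect=config.overlap_rect)
    out = []
    for obj in objects:
        f13, aligned = ft.extract_geometry(
            obj, circularity_threshold=config.circularity_threshold,
            elongation_threshold=config.elongation_threshold,
            n_strips=config.n_strips)
        spectrum = ft.fourier_spectrum(aligned, size=config.spectrum_size,
                                       n_radial=config.spectrum_bins,
                                       n_angular=config.spectrum_bins)
        out.append((obj, f13, spectrum.descriptor))
    return out


def _resolve_image(item):
    """(name, rgb, label) from a path, array, scene or (thing, label) pair."""
    label = None
    if isinstance(item, tuple) and len(item) == 2:
        item, label = item
    if isinstance(item, synth.SyntheticScene):
        if label is None and item.objects:
            labels = {o["label"] for o in item.objects}
            label = labels.pop() if len(labels) == 1 else None
        return "scene", item.image, label
    if isinstance(item, (str, Path)):
        return str(item), load_image(item), label
    return "array", np.asarray(item, dtype=float), label


def run_extract(images, config: PipelineConfig = PipelineConfig(),
                out_csv: str | Path | None = None) -> pd.DataFrame:
    """Preprocess + segment + measure a collection of images.

    ``images`` may hold file paths, RGB arrays, SyntheticScene objects, or
    ``(image, label)`` pairs.  Per-image failures are logged and skipped;
    if every image fails an error is raised.
    """
    rows = []
    n_failed = 0
    items = list(images)
    for img_idx, item in enumerate(items):
        try:
            name, rgb, label = _resolve_image(item)
            triples = extract_objects(rgb, config)
        except Exception as exc:
            n_failed += 1
            log.warning("image %d (%s): failed (%s); skipping", img_idx, item, exc)
            continue
        if not triples:
            log.warning("image %d (%s): no objects detected", img_idx, name)
        log.info("image %d (%s): %d object(s)", img_idx, name, len(triples))
        for obj, f13, desc in triples:
            row = {"image": name, "image_index": img_idx, "object_id": obj.index,
                   "overlapping": obj.overlapping_flag}
            row.update(dict(zip(GEOM_COLS, f13)))
            row.update(dict(zip(DESC_COLS, desc)))
            row["label"] = label
            rows.append(row)
    if items and n_failed == len(items):
        raise RuntimeError("all images failed extraction")
    df = pd.DataFrame(rows, columns=["image", "image_index", "object_id",
                                     "overlapping", *GEOM_COLS, *DESC_COLS, "label"])
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# training / evaluation


def _feature_matrix(df: pd.DataFrame, pca: ft.PCAModel) -> np.ndarray:
    geom = df[GEOM_COLS].to_numpy(dtype=float)
    desc = df[DESC_COLS].to_numpy(dtype=float)
    return np.hstack([geom, ft.project_pca(pca, desc)])


def run_train(table: pd.DataFrame, config: PipelineConfig = PipelineConfig()
              ) -> tuple[nn.MLPModel, ft.PCAModel, nn.TrainingState]:
    """Fit the descriptor PCA and train the 21-8-5 network on a labeled table."""
    df = table.dropna(subset=["label"])
    labels = sorted(df["label"].unique())
    if len(labels) < 2:
        raise ValueError("training table must contain at least 2 classes")
    pca = ft.fit_pca(df[DESC_COLS].to_numpy(dtype=float), k=config.pca_k)
    X = _feature_matrix(df, pca)
    label_map = tuple(sorted(set(nn.DEFAULT_LABELS) | set(labels))) \
        if set(labels) - set(nn.DEFAULT_LABELS) else nn.DEFAULT_LABELS
    data = nn.TrainingSet.from_labels(X, list(df["label"]), label_map=label_map)
    model = nn.init_mlp(config.seed, layer_sizes=(X.shape[1], 8, len(label_map)),
                        label_map=label_map,
                        unknown_threshold=config.unknown_threshold)
    model, state = nn.train(model, data, config.training)
    return model, pca, state


def run_evaluate(model: nn.MLPModel, pca: ft.PCAModel, test_table: pd.DataFrame,
                 config: PipelineConfig = PipelineConfig()) -> RunReport:
    """Classify a labeled test table and report the confusion matrix.

    Each test image contributes one prediction: its largest detected
    object.  Images without detections predict ``Unidentified``.
    """
    report = RunReport()
    preds, truth = [], []
    for img_idx, group in test_table.groupby("image_index"):
        report.object_counts[int(img_idx)] = len(group)
        best = group.loc[group["area"].idxmax()]
        x = _feature_matrix(best.to_frame().T, pca)[0]
        pred = nn.predict(model, x)
        preds.append(pred)
        truth.append(best["label"])
        report.predictions.append({"image_index": int(img_idx),
                                   "truth": best["label"], "prediction": pred})
    report.confusion = nn.evaluate(preds, truth, label_map=model.label_map)
    report.overall_accuracy = report.confusion["overall_accuracy"]
    return report


def run_benchmark(seed: int = 0, config: PipelineConfig | None = None,
                  include_debris: bool = False) -> RunReport:
    """The full synthetic benchmark: generate, extract, train, evaluate.

    Generates ``n_train_per_class`` training and ``n_test_per_class`` test
    single-alga scenes per genus (disjoint seeded streams), runs extraction
    on both splits, trains on the training features and reports test-set
    accuracy.  Scenes are processed one at a time to keep memory flat.
    """
    config = config or PipelineConfig()
    config = dataclasses.replace(config, seed=seed)
    train_ss, test_ss = synth.dataset_seed_sequences(seed)
    t0 = time.perf_counter()

    train_df = run_extract(
        synth.iter_single_object_scenes(config.n_train_per_class, train_ss,
                                        canvas=config.canvas), config)
    t1 = time.perf_counter()
    test_df = run_extract(
        synth.iter_single_object_scenes(config.n_test_per_class, test_ss,
                                        canvas=config.canvas), config)
    t2 = time.perf_counter()
    model, pca, state = run_train(train_df, config)
    t3 = time.perf_counter()
    report = run_evaluate(model, pca, test_df, config)
    t4 = time.perf_counter()
    report.train_rmse = state.train_rmse
    report.val_rmse = state.val_rmse
    report.timings = {"extract_train_s": t1 - t0, "extract_test_s": t2 - t1,
                      "train_s": t3 - t2, "evaluate_s": t4 - t3}
    if include_debris:
        debris_ss = np.random.SeedSequence(seed).spawn(3)[2]
        debris_df = run_extract(
            synth.iter_single_object_scenes(
                config.n_test_per_class, debris_ss, canvas=config.canvas,
                genera=(synth.DEBRIS,)), config)
        debris_report = run_evaluate(model, pca, debris_df, config)
        report.timings["debris"] = debris_report.confusion["per_class_accuracy"]
    return report
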