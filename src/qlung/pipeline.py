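"""High-level pipeline steps shared by the CLI, examples and scripts.

Each function is a thin composition of the stage modules, so a full run is:
phantom generation -> per-modality feature extraction -> training (hybrid or
traditional) -> evaluation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import Backbone, extract_dataset_features, tiny_backbone
from .config import merge_config
from .errors import ValidationError
from .imaging import CLASSES, PhantomConfig, generate_dataset
from .metrics import (collapse_binary, compute_metrics, confusion_3class, roc_auc)
from .trainer import HybridModel, TrainConfig, predict, train_hybrid, train_traditional

__all__ = [
    "phantom_config",
    "train_config",
    "generate_phantom_dataset",
    "extract_features",
    "train_from_manifest",
    "evaluate_model",
]


def phantom_config(config: dict) -> PhantomConfig:
    """Build a PhantomConfig from the (merged) run-config mapping."""
    data = config["data"]
    return PhantomConfig(
        n_subjects=data["n_subjects"],
        image_size=data["image_size"],
        class_proportions=tuple(data["class_proportions"]),
        noise_sd=data["noise_sd"],
        seed=config["seed"],
    )


def train_config(config: dict) -> TrainConfig:
    """Build a TrainConfig from the run-config mapping."""
    tr = config["train"]
    return TrainConfig(
        epochs=tr["epochs"],
        batch_size=tr["batch_size"],
        learning_rate=tr["learning_rate"],
        seed=config["seed"],
        train_frac=tr["train_frac"],
        val_frac=tr["val_frac"],
        test_frac=tr["test_frac"],
        patience=tr["patience"],
        n_var_layers=config["quantum"]["n_var_layers"],
        n_components=config["svd"]["n_components"],
        head_sizes=tuple(config["head"]["sizes"]),
    )


def generate_phantom_dataset(config: dict, out_dir) -> pd.DataFrame:
    """Write a phantom dataset per the run config; returns the manifest."""
    return generate_dataset(phantom_config(config), out_dir)


def default_backbones(config: dict) -> dict[str, Backbone]:
    """One tiny CNN per modality, with modality-distinct seeds."""
    base = config["backbone"]["seed"]
    return {"CXR": tiny_backbone(seed=base), "CT": tiny_backbone(seed=base + 1)}


def extract_features(manifest: pd.DataFrame, root_dir, config: dict
                     ) -> dict[str, pd.DataFrame]:
    """Per-modality feature tables for every manifest image."""
    backbones = default_backbones(config)
    return extract_dataset_features(
        backbones, manifest, root_dir=root_dir,
        resize_to=config["backbone"]["input_size"],
    )


def train_from_manifest(manifest: pd.DataFrame, root_dir, config: dict,
                        mode: str = "hybrid"):
    """Full extract -> fuse -> reduce -> train run from a manifest.

    Returns (model, history, features_by_modality).
    """
    if mode not in ("hybrid", "traditional"):
        raise ValidationError(f"mode must be hybrid or traditional, got {mode!r}")
    features = extract_features(manifest, root_dir, config)
    tc = train_config(config)
    train_fn = train_hybrid if mode == "hybrid" else train_traditional
    model, history = train_fn(features, tc)
    model.config["backbone_seed"] = config["backbone"]["seed"]
    model.config["backbone_input_size"] = config["backbone"]["input_size"]
    return model, history, features


def evaluate_model(model: HybridModel, features: dict[str, pd.DataFrame],
                   positive_class: str = "malignant",
                   subjects: list[str] | None = None) -> dict:
    """Confusion matrix, collapsed counts, metric report and ROC points.

    ``subjects`` restricts evaluation to a subject subset (e.g. the model's
    recorded test split); default is every subject in the feature tables.
    """
    if subjects is not None:
        features = {
            m: df[df["subject_id"].isin(subjects)].reset_index(drop=True)
            for m, df in features.items()
        }
    preds = predict(model, features)
    mat = confusion_3class(preds["label"], preds["predicted"])
    counts = collapse_binary(mat, positive_class=positive_class)
    y_bin = (preds["label"] == positive_class).to_numpy().astype(int)
    scores = preds[f"p_{positive_class}"].to_numpy()
    if y_bin.min() == y_bin.max():
        roc_points, auc = None, None
    else:
        roc_points, auc = roc_auc(y_bin, scores)
    report = compute_metrics(counts, auc=auc)
    return {
        "predictions": preds,
        "confusion_matrix": pd.DataFrame(mat, index=CLASSES, columns=CLASSES),
        "counts": counts,
        "report": report,
        "roc_points": roc_points,
    }
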