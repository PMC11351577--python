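"""Per-modality convolutional feature extraction.

Transfer-learning backbones act as fixed feature extractors: a forward pass
is run up to a named layer and the flattened activations become the
modality's feature vector (a^(l) = f(W^(l) x^(l-1) + b^(l)) per layer,
ReLU activations, and a trainable 3-logit head z = W^(f) a^(L) + b^(f) for
fine-tuning). Two routes are provided:

* a built-in tiny CNN (two conv+pool blocks and a 64-unit dense feature
  layer on 64x64 input) that is fully trainable at desk scale and backs all
  tests, and
* :class:`PretrainedBackboneAdapter`, a contract for externally supplied
  large backbones (VGG16/VGG19/InceptionV3/Xception/ResNet50/RepVGG) that
  declares each model's feature-extraction layer and dimension; the weights
  themselves are external artifacts and are never bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._nn import Adam, cross_entropy, he_init, relu, softmax
from .errors import IOErrorWithPath, ValidationError
from .imaging import ImageSample, load_grayscale
from .seeding import stage_rng

__all__ = [
    "relu",
    "LayerSpec",
    "BackboneSpec",
    "Backbone",
    "FeatureVector",
    "tiny_backbone",
    "finetune_head",
    "extract_dataset_features",
    "PretrainedBackboneAdapter",
    "PRETRAINED_LAYER_TABLE",
]


@dataclass
class LayerSpec:
    """One layer: kind in {conv, pool, dense}, its width and activation."""

    name: str
    kind: str
    width: int = 0  # conv: filters; dense: units; pool: window
    kernel: int = 3
    activation: str = "relu"  # {relu, sigmoid, none}


@dataclass
class BackboneSpec:
    """Layer list plus the named feature-extraction layer contract."""

    layers: list[LayerSpec]
    feature_layer_name: str
    feature_dim: int
    input_size: int
    seed: int = 0

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if names.count(self.feature_layer_name) != 1:
            raise ValidationError(
                f"feature_layer_name {self.feature_layer_name!r} must name exactly "
                f"one layer (have {names})"
            )


@dataclass
class FeatureVector:
    """A per-image real feature vector tagged with modality and subject."""

    values: np.ndarray
    modality: str
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector contains non-finite values")

    @property
    def dim(self) -> int:
        return self.values.size


def _activate(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return relu(x)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "none":
        return x
    raise ValidationError(f"unknown activation {kind!r}")


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (H, W, Cin); w: (k, k, Cin, Cout); valid padding, stride 1.
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    # win: (H-k+1, W-k+1, Cin, k, k)
    return np.einsum("ijckl,klco->ijo", win, w, optimize=True) + b


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return x.reshape(h // 2, 2, w // 2, 2, -1).max(axis=(1, 3))


class Backbone:
    """A concrete (spec, weights) pair with a deterministic forward pass.

    Weights are seeded He-normal at construction; the optional fine-tuned
    logits head (``head_w``, ``head_b``) is appended by
    :func:`finetune_head` and is the only trainable part by default.
    """

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        self.weights: dict[str, np.ndarray] = {}
        self.head_w: np.ndarray | None = None
        self.head_b: np.ndarray | None = None
        self.head_scaler: tuple[np.ndarray, np.ndarray] | None = None
        self.history: list[dict] = []
        rng = stage_rng(spec.seed, "backbone-init")
        c_in = 1
        size = spec.input_size
        for layer in spec.layers:
            if layer.kind == "conv":
                k = layer.kernel
                fan_in = k * k * c_in
                self.weights[layer.name + ".w"] = he_init(
                    rng, (k, k, c_in, layer.width), fan_in
                )
                self.weights[layer.name + ".b"] = np.zeros(layer.width)
                c_in = layer.width
                size = size - k + 1
            elif layer.kind == "pool":
                size = size // 2
            elif layer.kind == "dense":
                fan_in = size * size * c_in if size else c_in
                self.weights[layer.name + ".w"] = he_init(
                    rng, (layer.width, fan_in), fan_in
                )
                self.weights[layer.name + ".b"] = np.zeros(layer.width)
                c_in = layer.width
                size = 0  # flattened from here on
            else:
                raise ValidationError(f"unknown layer kind {layer.kind!r}")

    def _forward_to_feature(self, image: ImageSample) -> np.ndarray:
        if image.pixels.shape != (self.spec.input_size, self.spec.input_size):
            raise ValidationError(
                f"backbone expects {self.spec.input_size}x{self.spec.input_size} "
                f"input, got {image.pixels.shape[0]}x{image.pixels.shape[1]}"
            )
        x = image.pixels.astype(float)[:, :, None] / 255.0
        for layer in self.spec.layers:
            if layer.kind == "conv":
                x = _conv2d(x, self.weights[layer.name + ".w"],
                            self.weights[layer.name + ".b"])
                x = _activate(x, layer.activation)
            elif layer.kind == "pool":
                x = _maxpool2(x)
            elif layer.kind == "dense":
                flat = x.ravel()
                x = self.weights[layer.name + ".w"] @ flat + self.weights[layer.name + ".b"]
                x = _activate(x, layer.activation)
            if layer.name == self.spec.feature_layer_name:
                return np.asarray(x, dtype=float).ravel()
        raise ValidationError("feature layer not reached")  # pragma: no cover

    def features(self, image: ImageSample) -> FeatureVector:
        """Forward pass up to the feature layer; flattened activations."""
        vec = self._forward_to_feature(image)
        if vec.size != self.spec.feature_dim:
            raise ValidationError(
                f"feature layer produced dim {vec.size}, spec declares "
                f"{self.spec.feature_dim}"
            )
        return FeatureVector(vec, modality=image.modality, subject_id=image.subject_id)

    def logits(self, image: ImageSample) -> np.ndarray:
        if self.head_w is None:
            raise ValidationError("backbone has no fine-tuned head; call finetune_head")
        feat = self._forward_to_feature(image)
        if self.head_scaler is not None:
            mean, std = self.head_scaler
            feat = (feat - mean) / std
        return self.head_w @ feat + self.head_b


def tiny_backbone(seed: int = 0) -> Backbone:
    """The built-in desk-scale CNN: conv8-pool-conv16-pool-dense64 on 64x64."""
    spec = BackboneSpec(
        layers=[
            LayerSpec("conv1", "conv", width=8, kernel=3, activation="relu"),
            LayerSpec("pool1", "pool"),
            LayerSpec("conv2", "conv", width=16, kernel=3, activation="relu"),
            LayerSpec("pool2", "pool"),
            LayerSpec("dense_features", "dense", width=64, activation="relu"),
        ],
        feature_layer_name="dense_features",
        feature_dim=64,
        input_size=64,
        seed=seed,
    )
    return Backbone(spec)


def forward_features(backbone: Backbone, image: ImageSample) -> FeatureVector:
    """Functional alias for :meth:`Backbone.features`."""
    return backbone.features(image)


def finetune_head(
    backbone: Backbone,
    images: Sequence[ImageSample],
    labels: Sequence[int],
    epochs: int = 10,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
    n_classes: int = 3,
) -> Backbone:
    """Fine-tune a 3-logit softmax head on top of the frozen feature layer.

    The convolutional body stays frozen (features are computed once); only
    the appended dense head (W^(f), b^(f)) is trained, by minibatch Adam on
    softmax cross-entropy. Features are standardized (per-dimension z-score
    over the training set) before the logits layer; the scaler is stored on
    the backbone and applied at inference, so it is part of the head, not
    the frozen body. Returns the same backbone with ``head_w``, ``head_b``,
    ``head_scaler`` and a per-epoch ``history`` filled in.
    """
    labels = np.asarray(labels, dtype=int)
    if len(images) != labels.size:
        raise ValidationError("images and labels length mismatch")
    if np.unique(labels).size < 2:
        raise ValidationError("fine-tuning needs at least two classes present")

    if backbone.head_w is None:
        rng = stage_rng(seed, "finetune-head-init")
        dim = backbone.spec.feature_dim
        backbone.head_w = he_init(rng, (n_classes, dim), dim)
        backbone.head_b = np.zeros(n_classes)
    backbone.history = []
    if epochs == 0:
        return backbone

    feats = np.stack([backbone._forward_to_feature(im) for im in images])
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    backbone.head_scaler = (mean, std)
    feats = (feats - mean) / std
    opt = Adam([backbone.head_w, backbone.head_b], lr=lr)
    order_rng = stage_rng(seed, "finetune-head-batches")
    n = feats.shape[0]
    for epoch in range(1, epochs + 1):
        perm = order_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            fb, yb = feats[idx], labels[idx]
            logits = fb @ backbone.head_w.T + backbone.head_b
            probs = softmax(logits)
            correct += int((probs.argmax(axis=1) == yb).sum())
            losses += [cross_entropy(p, y) for p, y in zip(probs, yb)]
            delta = probs.copy()
            delta[np.arange(len(yb)), yb] -= 1.0
            gw = delta.T @ fb / len(yb)
            gb = delta.mean(axis=0)
            opt.step([gw, gb])
        backbone.history.append(
            {
                "epoch": epoch,
                "accuracy_pct": 100.0 * correct / n,
                "loss_pct": 100.0 * float(np.mean(losses)) / np.log(n_classes),
            }
        )
    return backbone


def extract_dataset_features(
    backbones: dict[str, Backbone], manifest: pd.DataFrame, root_dir=".",
    resize_to: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every manifest image through its modality's backbone.

    Returns one DataFrame per modality (columns: subject_id, label, then
    f0..f{d-1}), subject order preserved as in the manifest. With
    ``resize_to`` set, images are bilinearly resized to that side length
    before the forward pass (use the backbone's input size).
    """
    from .imaging import resize as _resize

    root = Path(root_dir)
    tables: dict[str, list] = {m: [] for m in backbones}
    for i, row in manifest.iterrows():
        modality = row["modality"]
        if modality not in backbones:
            raise ValidationError(f"no backbone configured for modality {modality!r}")
        path = root / row["path"]
        if not path.exists():
            raise IOErrorWithPath(path, f"manifest row {i}: image file missing")
        sample = load_grayscale(
            path, modality=modality, subject_id=row["subject_id"],
            label=row.get("label"),
        )
        if resize_to is not None:
            sample = _resize(sample, resize_to)
        fv = backbones[modality].features(sample)
        tables[modality].append(
            {"subject_id": fv.subject_id, "label": row.get("label"),
             **{f"f{j}": v for j, v in enumerate(fv.values)}}
        )
    return {m: pd.DataFrame(rows) for m, rows in tables.items()}


#: Feature-extraction layer contract for the six large pretrained models:
#: model -> (layer name, feature dimension, dimension after two-modality fusion).
PRETRAINED_LAYER_TABLE: dict[str, tuple[str, int, int]] = {
    "vgg16": ("Block5_conv3", 512, 1024),
    "vgg19": ("Block5_conv4", 512, 1024),
    "inceptionv3": ("mixed10", 2048, 4096),
    "xception": ("block14_sepconv2_act", 2048, 4096),
    "resnet50": ("conv5_block3_out", 2048, 4096),
    "repvgg": ("repvgg_block5", 2048, 4096),
}


class PretrainedBackboneAdapter:
    """Adapter contract for externally supplied large backbones.

    Declares the feature-extraction layer and dimensionality for each
    supported model. The heavy forward pass itself must be provided by the
    caller as ``forward_fn(image) -> 1-D array`` (e.g. wrapping a deep
    learning framework); without it the adapter can still answer the
    structural questions (layer name, dims) but refuses to extract.
    """

    def __init__(self, model_name: str,
                 forward_fn: Callable[[ImageSample], np.ndarray] | None = None):
        key = model_name.lower()
        if key not in PRETRAINED_LAYER_TABLE:
            raise ValidationError(
                f"unknown pretrained model {model_name!r}; "
                f"known: {sorted(PRETRAINED_LAYER_TABLE)}"
            )
        self.model_name = key
        self.feature_layer_name, self.feature_dim, self.fused_dim = (
            PRETRAINED_LAYER_TABLE[key]
        )
        self._forward_fn = forward_fn

    def features(self, image: ImageSample) -> FeatureVector:
        if self._forward_fn is None:
            raise ValidationError(
                f"adapter for {self.model_name!r} has no forward_fn; pretrained "
                "weights are external artifacts and are not bundled"
            )
        vec = np.asarray(self._forward_fn(image), dtype=float).ravel()
        if vec.size != self.feature_dim:
            raise ValidationError(
                f"{self.model_name} forward_fn returned dim {vec.size}, "
                f"declared {self.feature_dim}"
            )
        return FeatureVector(vec, modality=image.modality, subject_id=image.subject_id)
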