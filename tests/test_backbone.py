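"""Backbone forward-pass, fine-tuning and adapter contracts.

The forward pass is cross-checked against a brute-force per-layer oracle
written with explicit loops, independent of the im2col implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qlung.backbone import (Backbone, BackboneSpec, LayerSpec,
                            PretrainedBackboneAdapter, PRETRAINED_LAYER_TABLE,
                            extract_dataset_features, finetune_head, relu,
                            tiny_backbone)
from qlung.errors import IOErrorWithPath, ValidationError
from qlung.imaging import ImageSample, PhantomConfig, draw_latent, \
    generate_phantom_pair
from qlung.seeding import stage_rng


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_values(self, x, expected):
        assert relu(x) == expected

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    def test_idempotent(self, x):
        assert relu(relu(x)) == relu(x)


def constant_image(v, size=64, modality="CXR"):
    return ImageSample(np.full((size, size), v, dtype=np.uint8), modality=modality)


def oracle_forward(backbone: Backbone, image: ImageSample) -> np.ndarray:
    """Naive loop re-implementation of the forward pass (small inputs only)."""
    x = image.pixels.astype(float)[:, :, None] / 255.0
    for layer in backbone.spec.layers:
        if layer.kind == "conv":
            w = backbone.weights[layer.name + ".w"]
            b = backbone.weights[layer.name + ".b"]
            k, _, cin, cout = w.shape
            h_out, w_out = x.shape[0] - k + 1, x.shape[1] - k + 1
            out = np.zeros((h_out, w_out, cout))
            for i in range(h_out):
                for j in range(w_out):
                    for c in range(cout):
                        out[i, j, c] = np.sum(x[i : i + k, j : j + k, :] *
                                              w[:, :, :, c]) + b[c]
            x = np.maximum(out, 0) if layer.activation == "relu" else out
        elif layer.kind == "pool":
            h, w2 = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
            out = np.zeros((h // 2, w2 // 2, x.shape[2]))
            for i in range(h // 2):
                for j in range(w2 // 2):
                    out[i, j] = x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max(axis=(0, 1))
            x = out
        elif layer.kind == "dense":
            w = backbone.weights[layer.name + ".w"]
            b = backbone.weights[layer.name + ".b"]
            z = w @ x.ravel() + b
            x = np.maximum(z, 0) if layer.activation == "relu" else z
        if layer.name == backbone.spec.feature_layer_name:
            return np.asarray(x, dtype=float).ravel()
    raise AssertionError("feature layer not reached")


class TestForwardFeatures:
    def test_zero_weights_give_zero_features(self):
        bb = tiny_backbone(seed=0)
        for key in bb.weights:
            bb.weights[key] = np.zeros_like(bb.weights[key])
        fv = bb.features(constant_image(200))
        assert (fv.values == 0).all()

    def test_deterministic_repeat(self):
        bb = tiny_backbone(seed=4)
        img = constant_image(123)
        a, b = bb.features(img), bb.features(img)
        assert (a.values == b.values).all()

    def test_ones_filter_on_constant_image_sums_window(self):
        # 3x3 filter of ones on a constant image: every pre-activation is
        # 9 * (v / 255) under the documented input scaling.
        spec = BackboneSpec(
            layers=[LayerSpec("conv1", "conv", width=1, kernel=3, activation="none")],
            feature_layer_name="conv1", feature_dim=6 * 6, input_size=8, seed=0,
        )
        bb = Backbone(spec)
        bb.weights["conv1.w"] = np.ones((3, 3, 1, 1))
        bb.weights["conv1.b"] = np.zeros(1)
        v = 85
        fv = bb.features(constant_image(v, size=8))
        assert np.allclose(fv.values, 9 * v / 255.0, atol=1e-12)

    def test_matches_bruteforce_oracle_on_small_input(self):
        spec = BackboneSpec(
            layers=[
                LayerSpec("conv1", "conv", width=3, kernel=3, activation="relu"),
                LayerSpec("pool1", "pool"),
                LayerSpec("conv2", "conv", width=4, kernel=3, activation="relu"),
                LayerSpec("dense1", "dense", width=10, activation="relu"),
            ],
            feature_layer_name="dense1", feature_dim=10, input_size=16, seed=9,
        )
        bb = Backbone(spec)
        rng = np.random.default_rng(2)
        img = ImageSample(rng.integers(1, 256, (16, 16)).astype(np.uint8))
        assert np.allclose(bb.features(img).values, oracle_forward(bb, img),
                           atol=1e-10)

    def test_shape_mismatch_names_sizes(self):
        bb = tiny_backbone()
        with pytest.raises(ValidationError, match="64x64"):
            bb.features(constant_image(10, size=32))

    def test_feature_layer_must_be_unique(self):
        with pytest.raises(ValidationError):
            BackboneSpec(
                layers=[LayerSpec("a", "conv", 2), LayerSpec("a", "conv", 2)],
                feature_layer_name="a", feature_dim=1, input_size=8,
            )


def phantom_images(n_per_class, seed, size=64):
    """Labelled CXR phantoms for fine-tuning tests."""
    config = PhantomConfig(n_subjects=1, image_size=size, seed=seed)
    rng = stage_rng(seed, "ft-images")
    images, labels = [], []
    for label_idx, label in enumerate(("normal", "benign", "malignant")):
        for i in range(n_per_class):
            latent = draw_latent(f"S{label_idx}_{i}", label, config, rng)
            cxr, _ = generate_phantom_pair(latent, config, rng)
            images.append(cxr)
            labels.append(label_idx)
    return images, labels


class TestFinetuneHead:
    def test_zero_lr_leaves_weights_unchanged(self):
        bb = tiny_backbone(seed=1)
        images, labels = phantom_images(2, seed=1)
        finetune_head(bb, images, labels, epochs=1, lr=1e-3, seed=1)
        w0, b0 = bb.head_w.copy(), bb.head_b.copy()
        finetune_head(bb, images, labels, epochs=3, lr=0.0, seed=1)
        assert (bb.head_w == w0).all() and (bb.head_b == b0).all()

    def test_zero_epochs_is_identity_with_empty_history(self):
        bb = tiny_backbone(seed=2)
        images, labels = phantom_images(2, seed=2)
        finetune_head(bb, images, labels, epochs=0, seed=2)
        assert bb.history == []

    def test_body_weights_frozen_bit_identical(self):
        bb = tiny_backbone(seed=3)
        body_before = {k: v.copy() for k, v in bb.weights.items()}
        images, labels = phantom_images(3, seed=3)
        finetune_head(bb, images, labels, epochs=3, lr=1e-2, seed=3)
        for key, before in body_before.items():
            assert (bb.weights[key] == before).all()

    def test_single_class_rejected(self):
        bb = tiny_backbone()
        images, _ = phantom_images(2, seed=4)
        with pytest.raises(ValidationError):
            finetune_head(bb, images, [0] * len(images), epochs=1)

    def test_separable_phantoms_reach_90pct_training_accuracy(self):
        bb = tiny_backbone(seed=5)
        images, labels = phantom_images(20, seed=5)  # 60 images
        finetune_head(bb, images, labels, epochs=50, lr=5e-2, seed=5)
        assert bb.history[-1]["accuracy_pct"] >= 90.0


class TestExtractDatasetFeatures:
    def test_counts_and_dims(self, phantom_dir):
        out, manifest, _ = phantom_dir
        backbones = {"CXR": tiny_backbone(0), "CT": tiny_backbone(1)}
        tables = extract_dataset_features(backbones, manifest, root_dir=out)
        assert len(tables["CXR"]) == 30 and len(tables["CT"]) == 30
        feat_cols = [c for c in tables["CXR"].columns if c.startswith("f")]
        assert len(feat_cols) == 64

    def test_missing_file_reports_row(self, phantom_dir, tmp_path):
        out, manifest, _ = phantom_dir
        broken = manifest.copy()
        broken.loc[0, "path"] = "images/missing.png"
        backbones = {"CXR": tiny_backbone(0), "CT": tiny_backbone(1)}
        with pytest.raises(IOErrorWithPath, match="row 0"):
            extract_dataset_features(backbones, broken, root_dir=out)


class TestPretrainedAdapter:
    @pytest.mark.parametrize(
        "model,layer,dim",
        [("vgg16", "Block5_conv3", 512), ("repvgg", "repvgg_block5", 2048)],
    )
    def test_declared_layer_contract(self, model, layer, dim):
        adapter = PretrainedBackboneAdapter(model)
        assert adapter.feature_layer_name == layer
        assert adapter.feature_dim == dim
        assert adapter.fused_dim == 2 * dim

    def test_all_known_models_fuse_to_double_dim(self):
        for name, (_, dim, fused) in PRETRAINED_LAYER_TABLE.items():
            assert fused == 2 * dim

    def test_extraction_without_forward_fn_refuses(self):
        adapter = PretrainedBackboneAdapter("vgg16")
        with pytest.raises(ValidationError, match="forward_fn"):
            adapter.features(constant_image(10))

    def test_forward_fn_dim_checked(self):
        adapter = PretrainedBackboneAdapter("vgg16",
                                            forward_fn=lambda im: np.ones(7))
        with pytest.raises(ValidationError, match="512"):
            adapter.features(constant_image(10))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            PretrainedBackboneAdapter("alexnet")
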