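"""Shared fixtures: a small phantom dataset and separable feature tables."""

import numpy as np
import pandas as pd
import pytest

from qlung.config import merge_config
from qlung.imaging import generate_dataset, PhantomConfig


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """A 30-subject paired phantom dataset on disk (64x64, seed 7)."""
    out = tmp_path_factory.mktemp("phantom")
    config = PhantomConfig(n_subjects=30, image_size=64, seed=7)
    manifest = generate_dataset(config, out)
    return out, manifest, config


def make_feature_tables(n_per_class=12, dim=16, seed=3, spread=0.3):
    """Synthetic separable per-modality feature tables (no images involved).

    Class means sit at distinct corners of feature space; ``spread``
    controls within-class noise. Returns {"CXR": df, "CT": df}.
    """
    rng = np.random.default_rng(seed)
    classes = ("normal", "benign", "malignant")
    means = {c: rng.normal(0, 2.0, size=dim) for c in classes}
    tables = {}
    for modality in ("CXR", "CT"):
        rows = []
        i = 0
        for cls in classes:
            for _ in range(n_per_class):
                sid = f"S{i:04d}"
                vec = means[cls] + rng.normal(0, spread, size=dim)
                rows.append({"subject_id": sid, "label": cls,
                             **{f"f{j}": v for j, v in enumerate(vec)}})
                i += 1
        tables[modality] = pd.DataFrame(rows)
    return tables


@pytest.fixture()
def feature_tables():
    return make_feature_tables()


@pytest.fixture()
def default_config():
    return merge_config({})
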