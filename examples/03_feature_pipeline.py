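"""Classical front half of the pipeline: extract, fuse, compress.

A tiny seeded CNN turns each 64x64 phantom into a 64-dimensional feature
vector per modality; per-subject CXR and CT vectors are concatenated
(CXR block first) and the fused matrix is compressed by a mean-centered
truncated SVD to exactly five quantum features per subject.
"""

import tempfile

import numpy as np

from qlung.backbone import extract_dataset_features, tiny_backbone
from qlung.fusion import merge_dataset
from qlung.imaging import PhantomConfig, generate_dataset
from qlung.svd import fit as svd_fit, transform_matrix

with tempfile.TemporaryDirectory() as out:
    manifest = generate_dataset(PhantomConfig(n_subjects=12, seed=3), out)
    backbones = {"CXR": tiny_backbone(seed=0), "CT": tiny_backbone(seed=1)}
    tables = extract_dataset_features(backbones, manifest, root_dir=out)

feat_cols = [c for c in tables["CXR"].columns if c.startswith("f")]
print("per-modality feature dim:", len(feat_cols))

fused = merge_dataset(tables["CXR"], tables["CT"])
fused_cols = [c for c in fused.columns if c.startswith("f")]
print("fused dim (CXR || CT):", len(fused_cols))

x = fused[fused_cols].to_numpy(float)
projector = svd_fit(x)
q = transform_matrix(projector, x)
print("quantum features per subject:", q.shape[1])
print("singular values (energy ranking):", np.round(projector.singular_values, 3))
print("\nfirst subject's five quantum features:")
print(np.round(q[0], 4))

# The five numbers per subject are what the variational circuit embeds as
# rotation angles; the singular values show how much fused-feature variance
# each retained direction carries.
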