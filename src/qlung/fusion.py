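"""Cross-modality feature fusion.

Per-subject CXR and CT feature vectors are concatenated into one fused
vector, F_total = F^x || F^ct, with the CXR block first. Fusion doubles the
feature dimension (e.g. 512+512 -> 1024, 2048+2048 -> 4096) and is lossless:
the recorded split index recovers both inputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import FeatureVector
from .errors import ValidationError

__all__ = ["FusedVector", "merge", "merge_dataset"]


@dataclass
class FusedVector:
    """Concatenated two-modality feature vector; CXR block first."""

    values: np.ndarray
    subject_id: str
    split_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not 0 <= self.split_index <= self.values.size:
            raise ValidationError("split_index out of range")

    @property
    def dim(self) -> int:
        return self.values.size

    def unmerge(self) -> tuple[np.ndarray, np.ndarray]:
        """Recover (CXR block, CT block) exactly."""
        return self.values[: self.split_index], self.values[self.split_index :]


def merge(fx: FeatureVector, fct: FeatureVector) -> FusedVector:
    """Concatenate one subject's CXR and CT feature vectors, CXR first."""
    if fx.modality != "CXR":
        raise ValidationError(f"first argument must be CXR, got {fx.modality!r}")
    if fct.modality != "CT":
        raise ValidationError(f"second argument must be CT, got {fct.modality!r}")
    if fx.subject_id != fct.subject_id:
        raise ValidationError(
            f"subject mismatch: {fx.subject_id!r} vs {fct.subject_id!r}"
        )
    return FusedVector(
        np.concatenate([fx.values, fct.values]),
        subject_id=fx.subject_id,
        split_index=fx.dim,
    )


def merge_dataset(cxr: pd.DataFrame, ct: pd.DataFrame) -> pd.DataFrame:
    """Fuse per-modality feature tables keyed by subject_id.

    Both tables must cover exactly the same subjects; any subject missing a
    modality is reported by id rather than silently dropped. Output rows are
    in canonical (sorted) subject order with columns subject_id, label,
    split_index, then the fused feature columns f0..f{d-1}.
    """
    cxr_ids, ct_ids = set(cxr["subject_id"]), set(ct["subject_id"])
    unmatched = sorted(cxr_ids ^ ct_ids)
    if unmatched:
        raise ValidationError(
            f"subjects missing one modality: {unmatched}"
        )
    feat_cols_x = [c for c in cxr.columns if c.startswith("f")]
    feat_cols_ct = [c for c in ct.columns if c.startswith("f")]
    split = len(feat_cols_x)
    cxr_i = cxr.set_index("subject_id").sort_index()
    ct_i = ct.set_index("subject_id").sort_index()
    fused = np.hstack(
        [cxr_i[feat_cols_x].to_numpy(float), ct_i[feat_cols_ct].to_numpy(float)]
    )
    out = pd.DataFrame(fused, columns=[f"f{j}" for j in range(fused.shape[1])])
    out.insert(0, "subject_id", cxr_i.index.to_numpy())
    label = cxr_i["label"] if "label" in cxr_i.columns else None
    out.insert(1, "label", label.to_numpy() if label is not None else None)
    out.insert(2, "split_index", split)
    return out
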