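"""SVD compression of fused features to a handful of quantum features.

The fused feature matrix (one row per subject) is mean-centered and
factorized as M = U Sigma V^T; projecting onto the leading right singular
vectors (columns of V) gives the best least-squares low-rank summary of the
training features. The default keeps five components — one per qubit of the
downstream circuit.

The projector is fit on the training split only; inference applies the
stored mean and basis. A fixed sign convention (each basis column's
largest-magnitude entry nonnegative) makes results reproducible across
linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .fusion import FusedVector

__all__ = ["SVDProjector", "fit", "transform", "transform_matrix"]

N_QUANTUM_FEATURES = 5


@dataclass
class SVDProjector:
    """Fitted compression operator: mean, top-k right singular basis, values."""

    mean: np.ndarray          # (d,)
    basis: np.ndarray         # (d, k), orthonormal columns of V
    singular_values: np.ndarray  # (k,), nonincreasing, >= 0
    center: bool = True

    @property
    def input_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def save(self, path) -> None:
        """Persist as a JSON header plus an .npz array container."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        header = {
            "input_dim": self.input_dim,
            "n_components": self.n_components,
            "center": self.center,
            "sign_convention": "largest-magnitude entry nonnegative",
        }
        (path / "projector.json").write_text(json.dumps(header, indent=1))
        np.savez(path / "projector.npz", mean=self.mean, basis=self.basis,
                 singular_values=self.singular_values)

    @classmethod
    def load(cls, path) -> "SVDProjector":
        path = Path(path)
        header = json.loads((path / "projector.json").read_text())
        arrays = np.load(path / "projector.npz")
        return cls(
            mean=arrays["mean"], basis=arrays["basis"],
            singular_values=arrays["singular_values"], center=header["center"],
        )


def fit(train: np.ndarray, n_components: int = N_QUANTUM_FEATURES,
        center: bool = True) -> SVDProjector:
    """Fit the compressor on an (n_samples, d) training feature matrix.

    Requires n_samples >= n_components and d >= n_components. The matrix is
    column-mean centered (configurable off), thin-SVD factorized, and the
    leading ``n_components`` right singular vectors kept with their singular
    values.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2:
        raise ValidationError("training features must be a 2-D matrix")
    n, d = train.shape
    if n < n_components or d < n_components:
        raise ValidationError(
            f"need at least {n_components} samples and {n_components} feature "
            f"dimensions, got {n}x{d}"
        )
    if not np.all(np.isfinite(train)):
        raise ValidationError("training features contain non-finite entries")

    mean = train.mean(axis=0) if center else np.zeros(d)
    centered = train - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:n_components].T.copy()          # (d, k)
    sing = s[:n_components].copy()
    # Sign convention: flip each column so its largest-|.| entry is >= 0.
    for j in range(basis.shape[1]):
        pivot = np.argmax(np.abs(basis[:, j]))
        if basis[pivot, j] < 0:
            basis[:, j] *= -1.0
    return SVDProjector(mean=mean, basis=basis, singular_values=sing, center=center)


def transform(projector: SVDProjector, fused: FusedVector | np.ndarray) -> np.ndarray:
    """Project one fused vector to the quantum features basis^T (x - mean)."""
    values = fused.values if isinstance(fused, FusedVector) else np.asarray(fused, float)
    if values.size != projector.input_dim:
        raise ValidationError(
            f"fused dim {values.size} != projector dim {projector.input_dim}"
        )
    return projector.basis.T @ (values - projector.mean)


def transform_matrix(projector: SVDProjector, fused: np.ndarray) -> np.ndarray:
    """Project an (n, d) matrix of fused rows to (n, k) quantum features."""
    fused = np.asarray(fused, dtype=float)
    if fused.ndim != 2 or fused.shape[1] != projector.input_dim:
        raise ValidationError(
            f"expected (n, {projector.input_dim}) matrix, got {fused.shape}"
        )
    return (fused - projector.mean) @ projector.basis
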