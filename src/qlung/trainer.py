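"""Joint training of the variational circuit and dense head.

The pipeline order is fixed: stratified subject-level split, per-modality
feature fusion, SVD projector and angle scaler fit on the training split
only, then minibatch Adam updates of the circuit parameters (via the
parameter-shift Jacobian chained with the head's input gradient) and the
dense-head weights (ordinary backprop). The backbone stays frozen; features
are precomputed.

``train_traditional`` is the ablation baseline: the identical pipeline with
the quantum layer replaced by an identity pass-through of the five SVD
features into the same dense head, so hybrid-vs-traditional comparisons
differ in exactly one stage.

History rows report training accuracy and loss as percentages; the loss
percentage is 100 * cross-entropy / ln(3), i.e. normalized so a uniform
predictor scores 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, cross_entropy, softmax
from .errors import ValidationError
from .fusion import merge_dataset
from .head import DenseHead, head_forward, head_loss_and_grads
from .imaging import CLASSES
from .qlayer import CircuitSpec, fit_scaler, forward as qforward, gradients as qgrad
from .seeding import stage_rng
from .svd import SVDProjector, fit as svd_fit, transform_matrix

__all__ = ["TrainConfig", "HybridModel", "split_subjects", "train_hybrid",
           "train_traditional", "predict"]

_LOSS_NORM = float(np.log(3.0))


@dataclass
class TrainConfig:
    """Hyperparameters for hybrid / traditional training."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    patience: int | None = None
    n_var_layers: int = 2
    n_components: int = 5
    head_sizes: tuple[int, ...] = (100, 50, 20, 3)

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if min(fracs) < 0 or any(f <= 0 for f in (self.train_frac,)):
            raise ValidationError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1 within 1e-9")


@dataclass
class HybridModel:
    """Trained artifact: projector, circuit (or identity stage), head."""

    mode: str                      # "hybrid" | "traditional"
    projector: SVDProjector
    circuit: CircuitSpec
    head: DenseHead
    classes: tuple[str, ...] = CLASSES
    split: dict = field(default_factory=dict)   # subject ids per split
    config: dict = field(default_factory=dict)

    @property
    def n_quantum_params(self) -> int:
        return 0 if self.mode == "traditional" else self.circuit.n_params

    def quantum_stage(self, q_features: np.ndarray) -> np.ndarray:
        """Five SVD features -> five head inputs (circuit or identity)."""
        if self.mode == "traditional":
            return np.asarray(q_features, dtype=float)
        return qforward(self.circuit, q_features)

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "mode": self.mode,
            "quantum_stage": "identity" if self.mode == "traditional" else "vqc",
            "classes": list(self.classes),
            "circuit": self.circuit.to_dict(),
            "head": self.head.to_dict(),
            "split": self.split,
            "config": self.config,
        }
        (out_dir / "model.json").write_text(json.dumps(manifest, indent=1))
        self.projector.save(out_dir / "projector")
        return out_dir

    @classmethod
    def load(cls, out_dir) -> "HybridModel":
        out_dir = Path(out_dir)
        manifest = json.loads((out_dir / "model.json").read_text())
        return cls(
            mode=manifest["mode"],
            projector=SVDProjector.load(out_dir / "projector"),
            circuit=CircuitSpec.from_dict(manifest["circuit"]),
            head=DenseHead.from_dict(manifest["head"]),
            classes=tuple(manifest["classes"]),
            split=manifest["split"],
            config=manifest["config"],
        )


def split_subjects(subject_ids, labels, config: TrainConfig) -> dict[str, list[str]]:
    """Stratified subject-level train/val/test split, seeded."""
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    rng = stage_rng(config.seed, "split")
    out = {"train": [], "val": [], "test": []}
    for cls in np.unique(labels):
        ids = subject_ids[labels == cls]
        ids = ids[rng.permutation(ids.size)]
        n = ids.size
        n_train = int(round(config.train_frac * n))
        n_val = int(round(config.val_frac * n))
        out["train"] += ids[:n_train].tolist()
        out["val"] += ids[n_train : n_train + n_val].tolist()
        out["test"] += ids[n_train + n_val :].tolist()
    if not out["train"]:
        raise ValidationError("degenerate split: empty training set")
    return out


def _prepare(features_by_modality: dict[str, pd.DataFrame], config: TrainConfig):
    """Fuse, split, and fit projector + scaler on the training split only."""
    if set(features_by_modality) != {"CXR", "CT"}:
        raise ValidationError("need feature tables for exactly CXR and CT")
    fused = merge_dataset(features_by_modality["CXR"], features_by_modality["CT"])
    labels = fused["label"].to_numpy()
    known = set(CLASSES)
    bad = sorted({l for l in labels if l not in known})
    if bad:
        raise ValidationError(f"unknown labels in feature tables: {bad}")

    split = split_subjects(fused["subject_id"].to_numpy(), labels, config)
    feat_cols = [c for c in fused.columns if c.startswith("f")]
    x_all = fused[feat_cols].to_numpy(float)
    y_all = np.array([CLASSES.index(l) for l in labels])
    sid = fused["subject_id"].to_numpy()
    train_mask = np.isin(sid, split["train"])
    if np.unique(y_all[train_mask]).size < 2:
        raise ValidationError("training split must contain at least two classes")

    projector = svd_fit(x_all[train_mask], n_components=config.n_components)
    q_all = transform_matrix(projector, x_all)
    scaler = fit_scaler(q_all[train_mask])
    return fused, sid, x_all, y_all, q_all, train_mask, split, projector, scaler


def _epoch_eval(model: HybridModel, q: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Training accuracy (%) and normalized loss (%) under current weights."""
    correct, losses = 0, []
    for i in range(q.shape[0]):
        probs = head_forward(model.head, model.quantum_stage(q[i]))
        correct += int(np.argmax(probs) == y[i])
        losses.append(cross_entropy(probs, int(y[i])))
    n = q.shape[0]
    return 100.0 * correct / n, 100.0 * float(np.mean(losses)) / _LOSS_NORM


def _train(features_by_modality, config: TrainConfig, mode: str):
    (fused, sid, x_all, y_all, q_all, train_mask, split, projector,
     scaler) = _prepare(features_by_modality, config)

    rng = stage_rng(config.seed, f"{mode}-params")
    n_layers = config.n_var_layers if mode == "hybrid" else 0
    circuit = CircuitSpec(
        n_qubits=config.n_components,
        n_var_layers=n_layers,
        params=(rng.normal(0.0, 0.1, config.n_components * n_layers)
                if n_layers else None),
        scaler=scaler,
    )
    head = DenseHead(input_dim=config.n_components,
                     layer_sizes=tuple(config.head_sizes), seed=config.seed)
    model = HybridModel(mode=mode, projector=projector, circuit=circuit, head=head,
                        split=split, config=asdict(config))

    history_rows: list[dict] = []
    if config.epochs == 0:
        return model, pd.DataFrame(history_rows,
                                   columns=["epoch", "accuracy_pct", "loss_pct"])

    q_train, y_train = q_all[train_mask], y_all[train_mask]
    n = q_train.shape[0]
    head_params = head.parameters()
    if mode == "hybrid":
        opt_params = [circuit.params] + head_params
    else:
        opt_params = head_params
    opt = Adam(opt_params, lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    batch_rng = stage_rng(config.seed, f"{mode}-batches")

    best_loss, since_best = np.inf, 0
    for epoch in range(1, config.epochs + 1):
        perm = batch_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            g_theta = np.zeros_like(circuit.params)
            g_head = [np.zeros_like(p) for p in head_params]
            for i in idx:
                z5 = model.quantum_stage(q_train[i])
                _, gw, gb, gx = head_loss_and_grads(head, z5, int(y_train[i]))
                for acc, g in zip(g_head, gw + gb):
                    acc += g
                if mode == "hybrid" and circuit.n_params:
                    jac = qgrad(circuit, q_train[i])  # (5, n_params)
                    g_theta += gx @ jac
            scale = 1.0 / len(idx)
            grads = [g * scale for g in g_head]
            if mode == "hybrid":
                grads = [g_theta * scale] + grads
            opt.step(grads)

        acc_pct, loss_pct = _epoch_eval(model, q_train, y_train)
        history_rows.append(
            {"epoch": epoch, "accuracy_pct": acc_pct, "loss_pct": loss_pct}
        )
        if config.patience is not None:
            if loss_pct < best_loss - 1e-12:
                best_loss, since_best = loss_pct, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    history = pd.DataFrame(history_rows, columns=["epoch", "accuracy_pct", "loss_pct"])
    return model, history


def train_hybrid(features_by_modality: dict[str, pd.DataFrame],
                 config: TrainConfig) -> tuple[HybridModel, pd.DataFrame]:
    """Train the full quantum-classical model; returns (model, history)."""
    return _train(features_by_modality, config, "hybrid")


def train_traditional(features_by_modality: dict[str, pd.DataFrame],
                      config: TrainConfig) -> tuple[HybridModel, pd.DataFrame]:
    """Train the no-quantum ablation baseline on the identical pipeline."""
    return _train(features_by_modality, config, "traditional")


def predict(model: HybridModel,
            features_by_modality: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subject class probabilities and argmax labels.

    Input is the same per-modality feature-table pair used for training;
    both modalities must be present for every subject.
    """
    if set(features_by_modality) != {"CXR", "CT"}:
        raise ValidationError("prediction needs feature tables for CXR and CT")
    fused = merge_dataset(features_by_modality["CXR"], features_by_modality["CT"])
    feat_cols = [c for c in fused.columns if c.startswith("f")]
    q = transform_matrix(model.projector, fused[feat_cols].to_numpy(float))
    rows = []
    for i in range(q.shape[0]):
        probs = head_forward(model.head, model.quantum_stage(q[i]))
        rows.append(
            {
                "subject_id": fused["subject_id"].iloc[i],
                "label": fused["label"].iloc[i],
                "predicted": model.classes[int(np.argmax(probs))],
                **{f"p_{c}": float(p) for c, p in zip(model.classes, probs)},
            }
        )
    return pd.DataFrame(rows)
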