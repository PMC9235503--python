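"""The three predictor heads and their shared training configuration.

* Nystrom SVM: per-label linear classifiers with hinge loss, trained jointly
  by minibatch SGD on the Nystrom embedding, calibrated with per-label Platt
  sigmoids, exportable to dual (support-coefficient) form.
* Deep kernel: DNN on the Nystrom embedding (default hidden layers 2500 and
  8000, 50% dropout, l2 1e-7 on the output layer, Adam, batch 200, learning
  rate 1e-3, 25 epochs, sigmoid cross-entropy).
* Spectrum DNN: the same architecture on binned-spectrum + formula features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import sparse

from fpkit.models.nn import MLP, sigmoid
from fpkit.models.platt import (
    fit_platt,
    platt_probability,
    prior_platt_params,
)
from fpkit.nystrom import Embedding, NystromProjection

logger = logging.getLogger(__name__)

KINDS = ("nystrom_svm", "deep_kernel", "spectrum_dnn")


@dataclass
class TrainConfig:
    """Hyperparameters shared by all heads; defaults follow the deep kernel."""

    hidden_sizes: list[int] = field(default_factory=lambda: [2500, 8000])
    dropout_rate: float = 0.5
    l2_output: float = 1e-7
    learning_rate: float = 1e-3
    batch_size: int = 200
    epochs: int = 25
    seed: int = 0
    loss: str = "sigmoid_cross_entropy"
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PredictorModel:
    """A trained head: layer weights plus optional per-label Platt parameters."""

    kind: str
    mlp: MLP
    label_ids: list[str]
    platt_A: np.ndarray | None = None
    platt_B: np.ndarray | None = None
    constant_labels: list[str] = field(default_factory=list)
    projection_ref: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.mlp.layer_dims[-1] != len(self.label_ids):
            raise ValueError("output dimension must match label count")
        if self.kind == "nystrom_svm" and (
            self.platt_A is None or self.platt_B is None
        ):
            raise ValueError("SVM models require Platt parameters")

    @property
    def layer_dims(self) -> list[int]:
        return list(self.mlp.layer_dims)


@dataclass
class DualModel:
    """Kernel-space export of a Nystrom SVM.

    Decision values are computed from raw kernel rows against the landmarks:
    ``K @ coefficients + rowsum(K) * center_offset + intercept``. The
    center_offset term carries the intercept induced by centering the
    support coefficients, keeping decisions identical to the primal path.
    """

    support_coefficients: np.ndarray
    landmark_ids: list[str]
    center_offset: np.ndarray
    intercept: np.ndarray

    def decision_values(self, K_rows: np.ndarray) -> np.ndarray:
        K = np.asarray(K_rows, dtype=float)
        return (
            K @ self.support_coefficients
            + K.sum(axis=1, keepdims=True) * self.center_offset[None, :]
            + self.intercept[None, :]
        )


def count_parameters(layer_dims: Sequence[int], include_bias: bool = False) -> int:
    """Total weight count of a dense network with the given layer sizes."""
    dims = list(layer_dims)
    if len(dims) < 2:
        raise ValueError("need at least two layer dimensions")
    if any(d <= 0 for d in dims):
        raise ValueError("layer dimensions must be positive")
    total = sum(a * b for a, b in zip(dims[:-1], dims[1:]))
    if include_bias:
        total += sum(dims[1:])
    return total


def _resolve_xy(X, Y, label_ids):
    if isinstance(X, Embedding):
        X = X.features
    Y = np.asarray(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"feature rows ({X.shape[0]}) and label rows ({Y.shape[0]}) differ"
        )
    if label_ids is None:
        label_ids = [f"label_{j}" for j in range(Y.shape[1])]
    if len(label_ids) != Y.shape[1]:
        raise ValueError("label_ids must match the label matrix width")
    return X, Y.astype(float), list(label_ids)


def train_nystrom_svm(
    X,
    Y,
    weights: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    label_ids: Sequence[str] | None = None,
    projection_ref: str | None = None,
) -> PredictorModel:
    """Train the linear multi-label SVM head on an embedding.

    Minimizes per-label weighted hinge loss plus ``||W||^2 / (2 C)`` by
    minibatch SGD with a fixed learning rate; deterministic given
    ``cfg.seed``. Labels with a single class in training are flagged and
    calibrated to a smoothed constant prior. Per-label Platt parameters are
    fitted on the training decision values.
    """
    cfg = cfg or TrainConfig()
    X, Y, label_ids = _resolve_xy(X, Y, label_ids)
    n = X.shape[0]
    sw = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    mlp = MLP(
        [X.shape[1], len(label_ids)],
        seed=cfg.seed,
        dropout_rate=0.0,
        loss="hinge",
        svm_C=cfg.svm_C,
    )
    mlp.fit(
        X,
        Y,
        sw,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        optimizer="sgd",
        seed=cfg.seed,
    )
    decisions = mlp.decision_values(X)
    A = np.zeros(len(label_ids))
    B = np.zeros(len(label_ids))
    constant: list[str] = []
    for j, label in enumerate(label_ids):
        col = Y[:, j]
        if len(np.unique(col)) < 2:
            constant.append(label)
            prior = (col.sum() + 1.0) / (len(col) + 2.0)
            A[j], B[j] = prior_platt_params(prior)
        else:
            A[j], B[j] = fit_platt(decisions[:, j], col, sw)
    if constant:
        logger.warning(
            "%d labels had a single class and were trained as constants",
            len(constant),
        )
    return PredictorModel(
        kind="nystrom_svm",
        mlp=mlp,
        label_ids=label_ids,
        platt_A=A,
        platt_B=B,
        constant_labels=constant,
        projection_ref=projection_ref,
    )


def tune_svm_C(
    X,
    Y,
    weights: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    grid: Sequence[float] = (0.125, 0.5, 2.0, 8.0),
    val_fraction: float = 0.25,
) -> np.ndarray:
    """Per-label C selection on an inner validation split.

    Trains one model per grid value on an inner training subset and picks,
    per label, the C with the highest validation accuracy. Returns an array
    of per-label C values; callers typically retrain per C-group.
    """
    cfg = cfg or TrainConfig()
    X, Y, _ = _resolve_xy(X, Y, None)
    n = X.shape[0]
    sw = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    best_acc = np.full(Y.shape[1], -1.0)
    best_C = np.full(Y.shape[1], grid[0], dtype=float)
    for C in grid:
        sub_cfg = TrainConfig(**{**asdict(cfg), "svm_C": C})
        model = train_nystrom_svm(X[tr_idx], Y[tr_idx], sw[tr_idx], sub_cfg)
        pred = (model.mlp.decision_values(X[val_idx]) > 0).astype(float)
        acc = (pred == Y[val_idx]).mean(axis=0)
        better = acc > best_acc
        best_acc[better] = acc[better]
        best_C[better] = C
    return best_C


def primal_to_dual(model: PredictorModel, proj: NystromProjection) -> DualModel:
    """Fold the projection into the primal weights and center per label.

    The support coefficients are ``Gamma @ W`` minus their per-label column
    mean; the removed mean is retained as ``center_offset`` so that dual
    decision values match the primal path exactly.
    """
    if model.kind != "nystrom_svm":
        raise ValueError(f"primal_to_dual requires an SVM model, got {model.kind!r}")
    W = model.mlp.weights[-1]
    b = model.mlp.biases[-1]
    if proj.gamma.shape[1] != W.shape[0]:
        raise ValueError("projection rank does not match model input dimension")
    M = proj.gamma @ W
    mu = M.mean(axis=0)
    return DualModel(
        support_coefficients=M - mu[None, :],
        landmark_ids=list(proj.landmark_ids),
        center_offset=mu,
        intercept=b.copy(),
    )


def _train_dnn(
    kind: str,
    X,
    Y,
    weights,
    cfg: TrainConfig,
    label_ids,
    projection_ref=None,
) -> PredictorModel:
    X_feat, Y, label_ids = _resolve_xy(X, Y, label_ids)
    hidden = list(cfg.hidden_sizes)
    if not hidden:
        logger.warning("empty hidden_sizes: degenerating to a linear model")
    mlp = MLP(
        [X_feat.shape[1], *hidden, len(label_ids)],
        seed=cfg.seed,
        dropout_rate=cfg.dropout_rate,
        l2_output=cfg.l2_output,
        loss="sigmoid_cross_entropy",
    )
    n = X_feat.shape[0]
    sw = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    mlp.fit(
        X_feat,
        Y,
        sw,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        optimizer="adam",
        seed=cfg.seed,
    )
    return PredictorModel(
        kind=kind, mlp=mlp, label_ids=label_ids, projection_ref=projection_ref
    )


def train_deep_kernel(
    X,
    Y,
    weights: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    label_ids: Sequence[str] | None = None,
    projection_ref: str | None = None,
) -> PredictorModel:
    """Train the deep kernel head (DNN on the Nystrom embedding)."""
    return _train_dnn(
        "deep_kernel", X, Y, weights, cfg or TrainConfig(), label_ids, projection_ref
    )


def train_spectrum_dnn(
    X,
    Y,
    weights: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    label_ids: Sequence[str] | None = None,
) -> PredictorModel:
    """Train the spectrum-DNN baseline on binned + formula features."""
    if sparse.issparse(X):
        X = X.tocsr()
    return _train_dnn("spectrum_dnn", X, Y, weights, cfg or TrainConfig(), label_ids)


def predict_probabilities(model: PredictorModel, X) -> np.ndarray:
    """Per-compound, per-label probabilities in [0, 1].

    SVM models map decision values through their per-label Platt sigmoids;
    DNN models apply the logistic function to their output logits. Dropout
    is never applied at inference, so repeated calls are identical.
    """
    if isinstance(X, Embedding):
        X = X.features
    decisions = model.mlp.decision_values(X)
    if model.kind == "nystrom_svm":
        if model.platt_A is None or model.platt_B is None:
            raise ValueError("SVM model is missing Platt parameters")
        probs = np.column_stack(
            [
                platt_probability(decisions[:, j], model.platt_A[j], model.platt_B[j])
                for j in range(decisions.shape[1])
            ]
        )
        return probs
    return sigmoid(decisions)


def save_model(model: PredictorModel, path: str | Path) -> None:
    """Serialize a model to HDF5 (weights, dims, Platt params, label ids)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = model.kind
        fh.attrs["loss"] = model.mlp.loss
        fh.attrs["dropout_rate"] = model.mlp.dropout_rate
        fh.attrs["l2_output"] = model.mlp.l2_output
        fh.attrs["svm_C"] = model.mlp.svm_C
        if model.projection_ref:
            fh.attrs["projection_ref"] = model.projection_ref
        fh.create_dataset("layer_dims", data=np.array(model.mlp.layer_dims))
        fh.create_dataset("label_ids", data=np.array(model.label_ids, dtype="S"))
        fh.create_dataset(
            "constant_labels", data=np.array(model.constant_labels, dtype="S")
        )
        for i, (W, b) in enumerate(zip(model.mlp.weights, model.mlp.biases)):
            fh.create_dataset(f"W{i}", data=W)
            fh.create_dataset(f"b{i}", data=b)
        if model.platt_A is not None:
            fh.create_dataset("platt_A", data=model.platt_A)
            fh.create_dataset("platt_B", data=model.platt_B)


def load_model(path: str | Path) -> PredictorModel:
    """Load a model written by :func:`save_model`."""
    with h5py.File(path, "r") as fh:
        layer_dims = [int(d) for d in fh["layer_dims"][()]]
        mlp = MLP(
            layer_dims,
            dropout_rate=float(fh.attrs["dropout_rate"]),
            l2_output=float(fh.attrs["l2_output"]),
            loss=str(fh.attrs["loss"]),
            svm_C=float(fh.attrs["svm_C"]),
        )
        mlp.weights = [fh[f"W{i}"][()] for i in range(len(layer_dims) - 1)]
        mlp.biases = [fh[f"b{i}"][()] for i in range(len(layer_dims) - 1)]
        return PredictorModel(
            kind=str(fh.attrs["kind"]),
            mlp=mlp,
            label_ids=[s.decode() for s in fh["label_ids"][()]],
            platt_A=fh["platt_A"][()] if "platt_A" in fh else None,
            platt_B=fh["platt_B"][()] if "platt_B" in fh else None,
            constant_labels=[s.decode() for s in fh["constant_labels"][()]],
            projection_ref=str(fh.attrs.get("projection_ref") or "") or None,
        )
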