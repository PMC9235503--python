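"""Multi-label evaluation: MCC, BM, compound Tanimoto, micro averaging of
rare labels and structure-disjoint cross-validation folds."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Probability threshold used to binarize predictions.
BINARIZE_THRESHOLD = 0.5
#: Labels with fewer positives than this are pooled before computing metrics.
MICRO_MIN_POSITIVES = 10


@dataclass(frozen=True)
class ConfusionCounts:
    """Standard 2x2 confusion tally."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Ground-truth positives."""
        return self.tp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally a binary prediction vector against ground truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"prediction length {pred.shape} != truth length {truth.shape}"
        )
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient; NaN when a denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return float("nan")
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom))


def bm(c: ConfusionCounts) -> float:
    """Bookmakers informedness (Youden's J); NaN when a class is absent."""
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        return float("nan")
    return c.tp / pos + c.tn / neg - 1.0


def micro_average_pool(
    per_label_counts: Sequence[ConfusionCounts],
    min_positives: int = MICRO_MIN_POSITIVES,
) -> tuple[ConfusionCounts | None, list[int]]:
    """Pool rare labels (fewer than ``min_positives`` ground-truth positives).

    Returns the summed confusion counts of the pooled group (``None`` when no
    label is rare) and the indices of the individually retained labels.
    """
    if min_positives < 0:
        raise ValueError("min_positives must be non-negative")
    pooled: ConfusionCounts | None = None
    retained: list[int] = []
    for i, c in enumerate(per_label_counts):
        if c.positives < min_positives:
            pooled = c if pooled is None else pooled + c
        else:
            retained.append(i)
    return pooled, retained


def tanimoto_compound(pred_binary: np.ndarray, truth_binary: np.ndarray) -> float:
    """Jaccard index of the positive positions of two binary vectors.

    Two all-zero vectors are identical empty sets and score 1.0; this is
    flagged with a warning because no real fingerprint is all-zero.
    """
    pred = np.asarray(pred_binary).astype(bool)
    truth = np.asarray(truth_binary).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("vectors must have equal length")
    union = int((pred | truth).sum())
    if union == 0:
        warnings.warn("both vectors all-zero; Tanimoto defined as 1.0")
        return 1.0
    return int((pred & truth).sum()) / union


@dataclass
class FoldAssignment:
    """Structure-key to fold-index mapping for structure-disjoint CV."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, structure_key: str) -> int:
        return self.assignment[structure_key]

    def structures_in_fold(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def structure_disjoint_folds(
    structure_keys: Sequence[str], k: int, seed: int
) -> FoldAssignment:
    """Deal shuffled unique structures round-robin into ``k`` folds.

    All compounds sharing a structure key land in the same fold, so
    training and evaluation sets never share a 2D structure. Fold sizes are
    balanced within one structure.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = sorted(set(structure_keys))
    if len(unique) < k:
        raise ValueError(f"need at least {k} distinct structures, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {unique[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(assignment=assignment, k=k)


@dataclass
class EvaluationReport:
    """Per-label and aggregate metrics for one prediction matrix."""

    label_ids: list[str]
    per_label: list[ConfusionCounts]
    mean_mcc: float
    mean_bm: float
    mean_tanimoto: float
    n_undefined_mcc: int
    n_undefined_bm: int
    pooled: ConfusionCounts | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean_mcc": self.mean_mcc,
                    "mean_bm": self.mean_bm,
                    "mean_tanimoto": self.mean_tanimoto,
                    "n_undefined_mcc": self.n_undefined_mcc,
                    "n_undefined_bm": self.n_undefined_bm,
                    "n_labels": len(self.label_ids),
                },
                indent=2,
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\ttp\tfp\tfn\ttn\tmcc\tbm\tpositives\n")
            for label, c in zip(self.label_ids, self.per_label):
                fh.write(
                    f"{label}\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}\t"
                    f"{mcc(c):.6f}\t{bm(c):.6f}\t{c.positives}\n"
                )


def evaluate_predictions(
    probs: np.ndarray,
    truth: np.ndarray,
    label_ids: Sequence[str] | None = None,
    threshold: float = BINARIZE_THRESHOLD,
    micro_min_positives: int = MICRO_MIN_POSITIVES,
) -> EvaluationReport:
    """Full evaluation of a probability matrix against binary truth.

    Per-label MCC/BM are averaged over labels with at least
    ``micro_min_positives`` ground-truth positives plus one pooled
    pseudo-label for the rare ones; undefined (NaN) values are excluded from
    means and reported as counts. The Tanimoto is averaged over compounds.
    """
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth)
    if probs.shape != truth.shape:
        raise ValueError("probability and truth matrices must share a shape")
    if label_ids is None:
        label_ids = [f"label_{j}" for j in range(probs.shape[1])]
    pred = probs >= threshold
    per_label = [
        confusion_counts(pred[:, j], truth[:, j]) for j in range(probs.shape[1])
    ]
    pooled, retained = micro_average_pool(per_label, micro_min_positives)
    counts_for_mean = [per_label[i] for i in retained]
    if pooled is not None:
        counts_for_mean.append(pooled)
    mccs = np.array([mcc(c) for c in counts_for_mean])
    bms = np.array([bm(c) for c in counts_for_mean])
    tanimotos = np.array(
        [
            tanimoto_compound(pred[i], truth[i])
            for i in range(probs.shape[0])
            if (pred[i].any() or truth[i].any())
        ]
    )
    return EvaluationReport(
        label_ids=list(label_ids),
        per_label=per_label,
        mean_mcc=float(np.nanmean(mccs)) if np.isfinite(mccs).any() else float("nan"),
        mean_bm=float(np.nanmean(bms)) if np.isfinite(bms).any() else float("nan"),
        mean_tanimoto=float(tanimotos.mean()) if len(tanimotos) else float("nan"),
        n_undefined_mcc=int(np.isnan(mccs).sum()),
        n_undefined_bm=int(np.isnan(bms).sum()),
        pooled=pooled,
    )
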