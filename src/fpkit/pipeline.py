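"""End-to-end glue: kernel -> Nystrom embedding -> head -> evaluation.

Thin orchestration over the other modules, shared by the CLI, the test
suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fpkit.dbsearch import RankedResult, rank_candidates
from fpkit.evaluation import EvaluationReport, evaluate_predictions
from fpkit.kernels import (
    KernelMatrix,
    KernelSpec,
    kernel_matrix,
    normalize_kernel,
    self_kernels,
)
from fpkit.models import (
    PredictorModel,
    TrainConfig,
    predict_probabilities,
    train_deep_kernel,
    train_nystrom_svm,
)
from fpkit.nystrom import Embedding, NystromProjection, embed, fit_projection
from fpkit.spectra_data.model import CompoundRecord, FingerprintMatrix
from fpkit.synthetic_fixtures import Benchmark


def calibrated_train_configs() -> dict[str, TrainConfig]:
    """Head hyperparameters calibrated on the desk-scale benchmark.

    The deep kernel keeps the reference dropout/optimizer recipe with layer
    sizes and epochs scaled to the fixture; the SVM keeps plain minibatch
    SGD at learning rate 1e-3.
    """
    return {
        "deep_kernel": TrainConfig(
            hidden_sizes=[128, 256], epochs=40, batch_size=64, seed=1
        ),
        "nystrom_svm": TrainConfig(
            epochs=25, batch_size=200, learning_rate=1e-3, seed=1
        ),
    }


def normalized_kernel_block(
    rows: Sequence[CompoundRecord],
    landmarks: Sequence[CompoundRecord],
    spec: KernelSpec,
) -> KernelMatrix:
    """Cosine-normalized kernel block between ``rows`` and the landmarks."""
    if [r.compound_id for r in rows] == [l.compound_id for l in landmarks]:
        K = kernel_matrix(rows, None, spec)
        return normalize_kernel(K)
    K = kernel_matrix(rows, list(landmarks), spec)
    return normalize_kernel(
        K, diag_row=self_kernels(rows, spec), diag_col=self_kernels(landmarks, spec)
    )


@dataclass
class FittedEmbedder:
    """A fitted projection plus everything needed to embed new compounds."""

    landmarks: list[CompoundRecord]
    spec: KernelSpec
    projection: NystromProjection

    def transform(self, records: Sequence[CompoundRecord]) -> Embedding:
        K = normalized_kernel_block(records, self.landmarks, self.spec)
        return embed(K, self.projection)


def fit_embedder(
    landmarks: Sequence[CompoundRecord],
    spec: KernelSpec | None = None,
    eig_floor: float = 1e-10,
) -> FittedEmbedder:
    """Fit the Nystrom projection on the landmark (main training) set."""
    spec = spec or KernelSpec(name="ppk", type="ppk")
    K_AA = normalized_kernel_block(landmarks, landmarks, spec)
    proj = fit_projection(K_AA, eig_floor=eig_floor)
    return FittedEmbedder(landmarks=list(landmarks), spec=spec, projection=proj)


def labels_for(
    records: Sequence[CompoundRecord], fp: FingerprintMatrix
) -> np.ndarray:
    """Fingerprint rows aligned to a compound list via structure keys."""
    return fp.rows([r.structure_key for r in records]).astype(float)


@dataclass
class PipelineResult:
    model: PredictorModel
    embedder: FittedEmbedder
    report: EvaluationReport
    probabilities: np.ndarray
    ranked: list[RankedResult] | None = None


def train_and_evaluate(
    bench: Benchmark,
    head: str = "deep_kernel",
    cfg: TrainConfig | None = None,
    spec: KernelSpec | None = None,
    use_additional: bool = True,
    scoring: str | None = "loglik",
    eval_records: Sequence[CompoundRecord] | None = None,
) -> PipelineResult:
    """Run the full benchmark pipeline for one head.

    Trains on the merged landmark compounds plus (optionally) the unmerged
    replicate compounds with their reciprocal-sqrt weights, then evaluates
    probabilities on the held-out structures and, when ``scoring`` is set,
    ranks the candidate sets.
    """
    cfg = cfg or TrainConfig()
    embedder = fit_embedder(bench.train_records, spec=spec)
    records = list(bench.train_records)
    if use_additional:
        records += list(bench.additional_records)
    X_train = embedder.transform(records)
    Y_train = labels_for(records, bench.fingerprints)
    weights = np.array([r.sample_weight for r in records])
    label_ids = list(bench.fingerprints.labels)
    if head == "deep_kernel":
        model = train_deep_kernel(X_train, Y_train, weights, cfg, label_ids)
    elif head == "nystrom_svm":
        model = train_nystrom_svm(X_train, Y_train, weights, cfg, label_ids)
    else:
        raise ValueError(f"unknown head {head!r} for the kernel pipeline")

    eval_records = list(eval_records or bench.eval_records)
    X_eval = embedder.transform(eval_records)
    probs = predict_probabilities(model, X_eval)
    Y_eval = labels_for(eval_records, bench.fingerprints)
    report = evaluate_predictions(probs, Y_eval, label_ids)

    ranked = None
    if scoring is not None:
        prob_by_structure = {
            r.structure_key: probs[i] for i, r in enumerate(eval_records)
        }
        ranked = [
            rank_candidates(cs, prob_by_structure[cs.correct_key], scoring)
            for cs in bench.candidate_sets
            if cs.correct_key in prob_by_structure
        ]
    return PipelineResult(
        model=model,
        embedder=embedder,
        report=report,
        probabilities=probs,
        ranked=ranked,
    )


@dataclass
class NoiseRobustnessResult:
    """Mean MCCs of replicate-trained vs single-spectrum-trained models on
    clean and noise-perturbed evaluation spectra."""

    replicate_clean: float
    replicate_noisy: float
    single_clean: float
    single_noisy: float

    @property
    def replicate_drop(self) -> float:
        return self.replicate_clean - self.replicate_noisy

    @property
    def single_drop(self) -> float:
        return self.single_clean - self.single_noisy


def noise_robustness_experiment(
    bench: Benchmark,
    cfg: TrainConfig,
    eval_noise,
    seed: int = 0,
    head: str = "deep_kernel",
    spec: KernelSpec | None = None,
    cfg_single: TrainConfig | None = None,
    n_noise_realizations: int = 2,
) -> NoiseRobustnessResult:
    """Compare noise degradation of replicate-trained vs single-trained models.

    Both models share the same landmarks (one clean spectrum per training
    structure). The replicate-trained model additionally sees all noisy
    replicate spectra with reciprocal-sqrt weights; the single-trained model
    sees only the clean spectra (``cfg_single``, defaulting to ``cfg``, lets
    callers match the gradient-step budget of the larger training set).
    Both are evaluated on clean held-out spectra and on the same spectra
    with ``eval_noise`` applied; noisy MCCs are averaged over
    ``n_noise_realizations`` independent perturbations.
    """
    from fpkit.spectra_data.noise import simulate_noise

    spec = spec or KernelSpec(name="ppk", type="ppk")
    landmarks = bench.train_single_records
    embedder = fit_embedder(landmarks, spec=spec)
    fp = bench.fingerprints
    label_ids = list(fp.labels)

    def train_on(records, train_cfg):
        X = embedder.transform(records)
        Y = labels_for(records, fp)
        w = np.array([r.sample_weight for r in records])
        if head == "deep_kernel":
            return train_deep_kernel(X, Y, w, train_cfg, label_ids)
        return train_nystrom_svm(X, Y, w, train_cfg, label_ids)

    model_replicates = train_on(landmarks + list(bench.additional_records), cfg)
    model_single = train_on(landmarks, cfg_single or cfg)

    pool = bench.label_fragments.ravel().tolist()
    rng = np.random.default_rng(seed)
    clean_eval = list(bench.eval_single_records)
    Y_eval = labels_for(clean_eval, fp)

    def mean_mcc(model, records):
        probs = predict_probabilities(model, embedder.transform(records))
        return evaluate_predictions(probs, Y_eval, label_ids).mean_mcc

    replicate_noisy, single_noisy = [], []
    for _ in range(n_noise_realizations):
        noisy_eval = [
            CompoundRecord(
                spectrum=simulate_noise(
                    r.spectrum, pool, eval_noise, seed=int(rng.integers(0, 2**31 - 1))
                ),
                structure_key=r.structure_key,
                dataset_tag="eval",
            )
            for r in clean_eval
        ]
        replicate_noisy.append(mean_mcc(model_replicates, noisy_eval))
        single_noisy.append(mean_mcc(model_single, noisy_eval))

    return NoiseRobustnessResult(
        replicate_clean=mean_mcc(model_replicates, clean_eval),
        replicate_noisy=float(np.mean(replicate_noisy)),
        single_clean=mean_mcc(model_single, clean_eval),
        single_noisy=float(np.mean(single_noisy)),
    )
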