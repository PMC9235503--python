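"""Candidate-structure ranking from predicted probabilistic fingerprints."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

#: Probabilities are clamped to this range before any logarithm.
PROB_CLAMP = 1e-4

SCORINGS: dict[str, "ScoringFn"] = {}

ScoringFn = Callable[[np.ndarray, np.ndarray], float]


def register_scoring(name: str):
    """Register an external scoring function under ``name``."""

    def deco(fn: ScoringFn) -> ScoringFn:
        SCORINGS[name] = fn
        return fn

    return deco


@dataclass
class CandidateSet:
    """Candidates sharing a query's molecular formula."""

    query_id: str
    molecular_formula: str
    candidates: list[tuple[str, np.ndarray]]
    correct_key: str | None = None

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.candidates]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate candidate keys for query {self.query_id!r}")


@dataclass
class RankedResult:
    """Descending score order plus the (pessimistic) rank of the truth."""

    query_id: str
    ranking: list[tuple[str, float]]
    rank_of_correct: int | None = None


def clamp_probs(probs: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(probs, dtype=float), PROB_CLAMP, 1.0 - PROB_CLAMP)


@register_scoring("loglik")
def loglikelihood_score(probs: np.ndarray, candidate_fp: np.ndarray) -> float:
    """Per-label Bernoulli log-likelihood of the candidate fingerprint.

    sum_i [f_i log p_i + (1 - f_i) log(1 - p_i)], a diagonal (independence)
    approximation of covariance-based scorings.
    """
    p = clamp_probs(probs)
    f = np.asarray(candidate_fp, dtype=float)
    if p.shape != f.shape:
        raise ValueError(
            f"probability length {p.shape} != fingerprint length {f.shape}"
        )
    return float((f * np.log(p) + (1.0 - f) * np.log(1.0 - p)).sum())


@register_scoring("tanimoto")
def tanimoto_score(probs: np.ndarray, candidate_fp: np.ndarray) -> float:
    """Probabilistic Tanimoto: expected intersection over expected union."""
    p = clamp_probs(probs)
    f = np.asarray(candidate_fp, dtype=float)
    if p.shape != f.shape:
        raise ValueError(
            f"probability length {p.shape} != fingerprint length {f.shape}"
        )
    inter = float((p * f).sum())
    union = float((p + f - p * f).sum())
    if union <= 0:
        warnings.warn("empty expected union; Tanimoto score defined as 0")
        return 0.0
    return inter / union


@register_scoring("tanimoto_thresholded")
def thresholded_tanimoto_score(
    probs: np.ndarray, candidate_fp: np.ndarray, threshold: float = 0.5
) -> float:
    """Tanimoto between the 0.5-binarized prediction and the candidate."""
    p = (np.asarray(probs, dtype=float) >= threshold).astype(float)
    f = np.asarray(candidate_fp, dtype=float)
    if p.shape != f.shape:
        raise ValueError("length mismatch")
    union = float(np.maximum(p, f).sum())
    if union <= 0:
        return 0.0
    return float(np.minimum(p, f).sum()) / union


def rank_candidates(
    cs: CandidateSet,
    probs: np.ndarray,
    scoring: str | ScoringFn = "loglik",
) -> RankedResult:
    """Score and order candidates by descending score.

    Ties are handled pessimistically: the correct candidate's rank counts
    every candidate with a strictly greater score and every *other*
    candidate with an equal score, avoiding overstated identification rates.
    """
    if not cs.candidates:
        raise ValueError(f"empty candidate set for query {cs.query_id!r}")
    fn = SCORINGS[scoring] if isinstance(scoring, str) else scoring
    scores = [float(fn(probs, fp)) for _, fp in cs.candidates]
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], cs.candidates[i][0])
    )
    ranking = [(cs.candidates[i][0], scores[i]) for i in order]
    rank_of_correct: int | None = None
    if cs.correct_key is not None:
        by_key = {key: s for key, s in zip((k for k, _ in cs.candidates), scores)}
        if cs.correct_key in by_key:
            correct_score = by_key[cs.correct_key]
            worse_or_tied = sum(
                1
                for key, s in by_key.items()
                if s > correct_score or (s == correct_score and key != cs.correct_key)
            )
            rank_of_correct = 1 + worse_or_tied
    return RankedResult(
        query_id=cs.query_id, ranking=ranking, rank_of_correct=rank_of_correct
    )


def identification_rate(results: Sequence[RankedResult], k: int) -> float:
    """Fraction of queries whose correct structure ranks within the top k.

    Results without a rank (truth absent from the candidate list) count as
    misses.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not results:
        raise ValueError("no results to aggregate")
    hits = sum(
        1 for r in results if r.rank_of_correct is not None and r.rank_of_correct <= k
    )
    return hits / len(results)
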