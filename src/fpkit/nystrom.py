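"""Nystrom approximation: landmark eigendecomposition and feature embedding.

An n x n kernel matrix K is approximated from an m x m landmark block K_AA
and the cross block: K ~ [K_AA; K_AB^T] K_AA^{-1} [K_AA; K_AB^T]^T. Writing
the eigendecomposition K_AA = U S U^T, the projection Gamma = U_r S_r^{-1/2}
turns kernel rows against the landmarks into explicit feature vectors
X = K_rows @ Gamma with X X^T ~ K. Near-zero eigenvalues are discarded via a
relative floor (pseudo-inverse semantics) instead of inverting K_AA exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from fpkit.kernels import KernelMatrix

DEFAULT_EIG_FLOOR = 1e-10


@dataclass
class NystromProjection:
    """Landmark ids, projection matrix Gamma (m x r) and retained eigenvalues."""

    landmark_ids: list[str]
    gamma: np.ndarray
    eigenvalues: np.ndarray
    eig_floor: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        m, r = self.gamma.shape
        if m != len(self.landmark_ids):
            raise ValueError("gamma rows must match landmark count")
        if r != len(self.eigenvalues):
            raise ValueError("gamma columns must match retained eigenvalues")
        if r > m:
            raise ValueError("retained rank cannot exceed landmark count")
        if (self.eigenvalues <= 0).any():
            raise ValueError("retained eigenvalues must be strictly positive")
        if (np.diff(self.eigenvalues) > 0).any():
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def rank(self) -> int:
        return self.gamma.shape[1]


@dataclass
class Embedding:
    """Explicit feature rows for a compound set (n x r)."""

    compound_ids: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.compound_ids):
            raise ValueError("feature rows must match compound ids")

    @property
    def rank(self) -> int:
        return self.features.shape[1]


def fit_projection(
    K_AA: KernelMatrix,
    eig_floor: float = DEFAULT_EIG_FLOOR,
    max_rank: int | None = None,
) -> NystromProjection:
    """Eigendecompose the landmark block and build the projection matrix.

    Eigenpairs with eigenvalue >= ``eig_floor * lambda_max`` are retained;
    ``max_rank`` optionally truncates further (largest eigenvalues first).

    Raises
    ------
    ValueError
        If K_AA is asymmetric beyond 1e-8 or no eigenvalue clears the floor.
    """
    K_AA.check_symmetric(atol=1e-8)
    sym = (K_AA.values + K_AA.values.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(sym)
    # eigh returns ascending order; flip to descending.
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    lam_max = eigvals[0]
    if lam_max <= 0:
        raise ValueError("landmark kernel has no positive eigenvalue")
    keep = eigvals >= eig_floor * lam_max
    if not keep.any():
        raise ValueError("all eigenvalues fall below the relative floor")
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    if max_rank is not None:
        eigvals, eigvecs = eigvals[:max_rank], eigvecs[:, :max_rank]
    gamma = eigvecs / np.sqrt(eigvals)[None, :]
    return NystromProjection(
        landmark_ids=list(K_AA.row_ids),
        gamma=gamma,
        eigenvalues=eigvals,
        eig_floor=eig_floor,
    )


def embed(K_rows: KernelMatrix, proj: NystromProjection) -> Embedding:
    """Project kernel rows against the landmarks into feature space.

    ``K_rows`` must have its columns aligned with (and identical to) the
    projection's landmark order; no silent reordering is performed.
    """
    if K_rows.col_ids != proj.landmark_ids:
        raise ValueError(
            "kernel columns do not match the projection's landmark order"
        )
    return Embedding(
        compound_ids=list(K_rows.row_ids),
        features=K_rows.values @ proj.gamma,
    )


def reconstruct_kernel(e1: Embedding, e2: Embedding | None = None) -> KernelMatrix:
    """Approximate kernel block from embeddings: values = X1 @ X2^T."""
    if e2 is None:
        e2 = e1
    if e1.rank != e2.rank:
        raise ValueError(
            f"embedding ranks differ: {e1.rank} vs {e2.rank}"
        )
    return KernelMatrix(
        list(e1.compound_ids),
        list(e2.compound_ids),
        e1.features @ e2.features.T,
        name="nystrom_reconstruction",
    )


def save_projection(proj: NystromProjection, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gamma", data=proj.gamma)
        fh.create_dataset("eigenvalues", data=proj.eigenvalues)
        fh.create_dataset(
            "landmark_ids", data=np.array(proj.landmark_ids, dtype="S")
        )
        fh.attrs["eig_floor"] = proj.eig_floor


def load_projection(path: str | Path) -> NystromProjection:
    with h5py.File(path, "r") as fh:
        return NystromProjection(
            landmark_ids=[s.decode() for s in fh["landmark_ids"][()]],
            gamma=fh["gamma"][()],
            eigenvalues=fh["eigenvalues"][()],
            eig_floor=float(fh.attrs["eig_floor"]),
        )
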