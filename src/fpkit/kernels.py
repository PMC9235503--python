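"""Compound-compound kernel matrices.

The probability product kernel (PPK) on spectra is computed natively: each
spectrum is viewed as a Gaussian mixture over m/z with mixing weights given
by normalized intensities, and the kernel is the integral of the product of
the two mixtures. Domain-specific kernels (e.g. on fragmentation trees)
enter the pipeline as precomputed matrices and are combined with the PPK by
weighted summation after per-kernel cosine normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from fpkit.spectra_data.model import CompoundRecord, Spectrum

#: Relative tolerance for negative eigenvalues regarded as numerical noise.
PSD_RTOL = 1e-8
#: PPK contributions beyond this many sigmas are dropped (< 1e-16 relative).
_PPK_CUTOFF_SIGMAS = 13.0


@dataclass
class KernelMatrix:
    """A (possibly rectangular) kernel matrix with compound identifiers."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    name: str = "kernel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match id lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def check_symmetric(self, atol: float = 1e-10) -> None:
        if not self.is_square:
            raise ValueError("symmetry is only defined for square kernels")
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError(f"kernel {self.name!r} is not symmetric within {atol}")

    def check_psd(self, rtol: float = PSD_RTOL) -> None:
        """Raise if the smallest eigenvalue is below ``-rtol * lambda_max``."""
        self.check_symmetric(atol=1e-8)
        eigvals = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        lam_max = max(eigvals[-1], 0.0)
        if eigvals[0] < -rtol * max(lam_max, 1e-30):
            raise ValueError(
                f"kernel {self.name!r} has eigenvalue {eigvals[0]:.3e} below "
                f"-{rtol:g} * lambda_max ({lam_max:.3e})"
            )


@dataclass
class KernelSpec:
    """Declarative description of one kernel in a combination.

    ``type`` is ``"ppk"`` (computed natively; ``params["sigma_m"]`` is the
    Gaussian mass bandwidth in Da) or ``"precomputed"`` (``params["path"]``
    points at an HDF5/TSV matrix).
    """

    name: str
    type: str = "ppk"
    params: dict = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in ("ppk", "precomputed"):
            raise ValueError(f"unknown kernel type {self.type!r}")
        if self.weight < 0:
            raise ValueError("kernel weight must be non-negative")
        if self.type == "ppk" and self.params.get("sigma_m", DEFAULT_SIGMA_M) <= 0:
            raise ValueError("ppk sigma_m must be positive")


DEFAULT_SIGMA_M = 0.01


def _mixture(s: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    if not s.peaks:
        raise ValueError(f"empty spectrum {s.compound_id!r} has no PPK value")
    mz = s.mz
    w = s.intensities
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum intensities sum to zero")
    return mz, w / total


def ppk(a: Spectrum, b: Spectrum, sigma_m: float = DEFAULT_SIGMA_M) -> float:
    """Probability product kernel between two spectra.

    k(a, b) = sum_ij w_i w'_j exp(-(mz_i - mz'_j)^2 / (4 sigma_m^2))
              / sqrt(4 pi sigma_m^2)

    with intensities normalized to sum 1. For identical single-peak spectra
    this evaluates to 1 / sqrt(4 pi sigma_m^2).
    """
    if sigma_m <= 0:
        raise ValueError("sigma_m must be positive")
    mz_a, w_a = _mixture(a)
    mz_b, w_b = _mixture(b)
    diff = mz_a[:, None] - mz_b[None, :]
    gauss = np.exp(-(diff**2) / (4.0 * sigma_m**2))
    norm = np.sqrt(4.0 * np.pi * sigma_m**2)
    return float((w_a[:, None] * w_b[None, :] * gauss).sum() / norm)


def _ppk_matrix(
    rows: Sequence[Spectrum], cols: Sequence[Spectrum], sigma_m: float
) -> np.ndarray:
    """Vectorized PPK Gram matrix.

    All column-side peaks are pooled into one sorted array; for each row
    peak only column peaks within the truncation window contribute
    (contributions beyond it are below double precision).
    """
    col_mz_parts: list[np.ndarray] = []
    col_w_parts: list[np.ndarray] = []
    col_idx_parts: list[np.ndarray] = []
    for j, s in enumerate(cols):
        mz, w = _mixture(s)
        col_mz_parts.append(mz)
        col_w_parts.append(w)
        col_idx_parts.append(np.full(len(mz), j, dtype=np.int64))
    col_mz = np.concatenate(col_mz_parts)
    col_w = np.concatenate(col_w_parts)
    col_idx = np.concatenate(col_idx_parts)
    order = np.argsort(col_mz)
    col_mz, col_w, col_idx = col_mz[order], col_w[order], col_idx[order]

    window = _PPK_CUTOFF_SIGMAS * sigma_m
    norm = np.sqrt(4.0 * np.pi * sigma_m**2)
    out = np.zeros((len(rows), len(cols)))
    for i, s in enumerate(rows):
        mz, w = _mixture(s)
        lo = np.searchsorted(col_mz, mz - window, side="left")
        hi = np.searchsorted(col_mz, mz + window, side="right")
        acc = out[i]
        for m, wi, a, b in zip(mz, w, lo, hi):
            if a == b:
                continue
            gauss = np.exp(-((col_mz[a:b] - m) ** 2) / (4.0 * sigma_m**2))
            np.add.at(acc, col_idx[a:b], wi * col_w[a:b] * gauss / norm)
    return out


def kernel_matrix(
    rows: Sequence[CompoundRecord],
    cols: Sequence[CompoundRecord] | None,
    spec: KernelSpec,
) -> KernelMatrix:
    """Evaluate a kernel between two compound lists.

    With ``cols=None`` (or identical ids) the square case is enforced
    symmetric. Precomputed kernels are looked up by compound id; missing
    ids raise an error listing them.
    """
    symmetric = cols is None
    if cols is None:
        cols = rows
    row_ids = [r.compound_id for r in rows]
    col_ids = [c.compound_id for c in cols]
    if spec.type == "ppk":
        sigma_m = float(spec.params.get("sigma_m", DEFAULT_SIGMA_M))
        values = _ppk_matrix(
            [r.spectrum for r in rows], [c.spectrum for c in cols], sigma_m
        )
        if symmetric or row_ids == col_ids:
            values = (values + values.T) / 2.0
    else:
        stored = load_kernel(spec.params["path"])
        values = _lookup_block(stored, row_ids, col_ids)
    return KernelMatrix(row_ids, col_ids, values, name=spec.name)


def _lookup_block(
    stored: KernelMatrix, row_ids: Sequence[str], col_ids: Sequence[str]
) -> np.ndarray:
    row_index = {cid: i for i, cid in enumerate(stored.row_ids)}
    col_index = {cid: i for i, cid in enumerate(stored.col_ids)}
    missing = [cid for cid in row_ids if cid not in row_index]
    missing += [cid for cid in col_ids if cid not in col_index]
    if missing:
        raise KeyError(
            f"precomputed kernel {stored.name!r} is missing ids: {sorted(set(missing))}"
        )
    ri = np.array([row_index[c] for c in row_ids])
    ci = np.array([col_index[c] for c in col_ids])
    return stored.values[np.ix_(ri, ci)]


def self_kernels(records: Sequence[CompoundRecord], spec: KernelSpec) -> np.ndarray:
    """Diagonal self-similarities k(x, x) needed for cosine normalization."""
    if spec.type == "ppk":
        sigma_m = float(spec.params.get("sigma_m", DEFAULT_SIGMA_M))
        return np.array([ppk(r.spectrum, r.spectrum, sigma_m) for r in records])
    stored = load_kernel(spec.params["path"])
    ids = [r.compound_id for r in records]
    return np.diag(_lookup_block(stored, ids, ids)).copy()


def normalize_kernel(
    K: KernelMatrix,
    diag_row: np.ndarray | None = None,
    diag_col: np.ndarray | None = None,
) -> KernelMatrix:
    """Cosine normalization: values[i, j] / sqrt(diag_row[i] * diag_col[j]).

    For a square kernel the diagonals default to the matrix diagonal and the
    result has unit diagonal. Rectangular kernels require explicit self-
    kernel values for rows and columns.
    """
    if diag_row is None or diag_col is None:
        if not K.is_square:
            raise ValueError(
                "rectangular kernels need explicit diag_row and diag_col"
            )
        diag = np.diag(K.values).copy()
        diag_row = diag if diag_row is None else diag_row
        diag_col = diag if diag_col is None else diag_col
    diag_row = np.asarray(diag_row, dtype=float)
    diag_col = np.asarray(diag_col, dtype=float)
    if (diag_row <= 0).any() or (diag_col <= 0).any():
        raise ValueError("all self-kernel values must be positive")
    values = K.values / np.sqrt(diag_row[:, None] * diag_col[None, :])
    return KernelMatrix(K.row_ids, K.col_ids, values, name=K.name + "_norm")


def combine_kernels(
    matrices: Sequence[KernelMatrix],
    weights: Sequence[float] | None = None,
) -> KernelMatrix:
    """Weighted sum of kernels sharing the same row/col ids.

    Weights are rescaled to sum 1; callers normalize each kernel first
    (see :func:`normalize_kernel`). PSD-ness is preserved for PSD inputs
    since weights are non-negative.
    """
    if not matrices:
        raise ValueError("no kernels to combine")
    if weights is None:
        weights = [1.0] * len(matrices)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(matrices):
        raise ValueError("one weight per kernel required")
    if (weights < 0).any():
        raise ValueError("kernel weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("kernel weights must sum to a positive value")
    weights = weights / total
    first = matrices[0]
    for K in matrices[1:]:
        if K.row_ids != first.row_ids or K.col_ids != first.col_ids:
            raise ValueError(
                f"kernel {K.name!r} has mismatched compound ids"
            )
    values = sum(w * K.values for w, K in zip(weights, matrices))
    return KernelMatrix(
        list(first.row_ids), list(first.col_ids), values, name="combined"
    )


def alignment_weights(
    matrices: Sequence[KernelMatrix], target: np.ndarray
) -> np.ndarray:
    """Centered-kernel-alignment weights against a target similarity matrix.

    Each square kernel is centered and scored by its alignment with the
    (centered) target; negative alignments are clipped to zero and the
    weights normalized to sum 1. This is an optional alternative to uniform
    weights.
    """
    target = np.asarray(target, dtype=float)

    def center(M: np.ndarray) -> np.ndarray:
        n = M.shape[0]
        H = np.eye(n) - np.ones((n, n)) / n
        return H @ M @ H

    tc = center(target)
    tnorm = np.linalg.norm(tc)
    scores = []
    for K in matrices:
        kc = center(K.values)
        denom = np.linalg.norm(kc) * tnorm
        scores.append(float((kc * tc).sum() / denom) if denom > 0 else 0.0)
    scores = np.clip(np.asarray(scores), 0.0, None)
    if scores.sum() <= 0:
        return np.full(len(matrices), 1.0 / len(matrices))
    return scores / scores.sum()


def save_kernel(K: KernelMatrix, path: str | Path) -> None:
    """Write a kernel matrix to HDF5 (datasets: values, row_ids, col_ids)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=K.values)
        fh.create_dataset("row_ids", data=np.array(K.row_ids, dtype="S"))
        fh.create_dataset("col_ids", data=np.array(K.col_ids, dtype="S"))
        fh.attrs["name"] = K.name


def load_kernel(path: str | Path) -> KernelMatrix:
    """Load a kernel matrix from HDF5 or TSV (matrix with header row/col)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return KernelMatrix(
                [s.decode() for s in fh["row_ids"][()]],
                [s.decode() for s in fh["col_ids"][()]],
                fh["values"][()],
                name=str(fh.attrs.get("name", path.stem)),
            )
    # TSV fallback: first row = col ids, first column = row ids.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        row_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return KernelMatrix(row_ids, header, np.array(rows), name=path.stem)


def save_kernel_tsv(K: KernelMatrix, path: str | Path) -> None:
    """TSV fallback writer matching :func:`load_kernel`'s TSV dialect."""
    with open(path, "w") as fh:
        fh.write("compound_id\t" + "\t".join(K.col_ids) + "\n")
        for rid, row in zip(K.row_ids, K.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
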