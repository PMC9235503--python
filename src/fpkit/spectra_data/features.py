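"""Featurization of spectra for the spectrum-DNN baseline.

A spectrum becomes two concatenated binned vectors: raw m/z bins and
precursor-minus-m/z bins, both carrying the square root of relative peak
intensity. Molecular formulas become dense element-count vectors normalized
by per-element training standard deviations.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from fpkit.spectra_data.model import Spectrum

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.005
DEFAULT_MAX_MASS = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``"C6H12O6"`` into ``{"C": 6, "H": 12, "O": 6}``."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def n_bins(bin_width: float = DEFAULT_BIN_WIDTH, max_mass: float = DEFAULT_MAX_MASS) -> int:
    """Number of bins per vector for a given width and mass ceiling."""
    return int(np.ceil(max_mass / bin_width))


def bin_spectrum_features(
    s: Spectrum,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_mass: float = DEFAULT_MAX_MASS,
) -> sparse.csr_matrix:
    """Binned sparse feature vector of one spectrum.

    The first half of the vector bins raw m/z values; the second half bins
    precursor m/z minus fragment m/z (neutral-loss view). Bin value is the
    square root of relative intensity (relative to the base peak); peaks
    colliding in a bin are combined by maximum. Peaks above ``max_mass`` are
    logged and dropped.

    Returns a ``1 x 2*n_bins`` CSR matrix.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nb = n_bins(bin_width, max_mass)
    data: dict[int, float] = {}
    if s.peaks:
        mz = s.mz
        inten = s.intensities
        rel = inten / inten.max() if inten.max() > 0 else inten
        feat = np.sqrt(rel)
        for m, f in zip(mz, feat):
            if m >= max_mass:
                logger.debug("peak at m/z %.4f above max_mass %.1f dropped", m, max_mass)
                continue
            idx = int(m / bin_width)
            data[idx] = max(data.get(idx, 0.0), f)
        if s.precursor_mz is not None:
            for m, f in zip(mz, feat):
                loss = s.precursor_mz - m
                if loss < 0 or loss >= max_mass:
                    continue
                idx = nb + int(loss / bin_width)
                data[idx] = max(data.get(idx, 0.0), f)
    if not data:
        return sparse.csr_matrix((1, 2 * nb))
    cols = np.fromiter(data.keys(), dtype=np.int64)
    vals = np.fromiter(data.values(), dtype=float)
    rows = np.zeros_like(cols)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(1, 2 * nb))


def formula_feature_vector(
    formula: Mapping[str, int],
    element_order: Sequence[str],
    stds: Mapping[str, float],
) -> np.ndarray:
    """Element-count vector normalized by per-element training standard deviations.

    Elements with zero training standard deviation are constant in training
    and carry no information; they must not appear in ``element_order``.

    Raises
    ------
    ValueError
        If the formula contains an element outside ``element_order``.
    """
    unknown = set(formula) - set(element_order)
    if unknown:
        raise ValueError(
            f"formula contains elements outside the training alphabet: "
            f"{sorted(unknown)}"
        )
    out = np.zeros(len(element_order), dtype=float)
    for j, element in enumerate(element_order):
        std = stds.get(element, 1.0)
        if std <= 0:
            raise ValueError(f"element {element!r} has non-positive std {std}")
        out[j] = formula.get(element, 0) / std
    return out


def fit_formula_normalization(
    formulas: Sequence[Mapping[str, int]]
) -> tuple[list[str], dict[str, float]]:
    """Estimate the element alphabet and per-element stds from training formulas.

    Elements whose counts are constant across training (std 0) are dropped
    from the alphabet.
    """
    elements = sorted({e for f in formulas for e in f})
    counts = np.array(
        [[f.get(e, 0) for e in elements] for f in formulas], dtype=float
    )
    stds = counts.std(axis=0)
    order = [e for e, s in zip(elements, stds) if s > 0]
    return order, {e: float(s) for e, s in zip(elements, stds) if s > 0}


def featurize_records(
    spectra: Sequence[Spectrum],
    formulas: Sequence[Mapping[str, int]] | None = None,
    element_order: Sequence[str] | None = None,
    stds: Mapping[str, float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_mass: float = DEFAULT_MAX_MASS,
) -> sparse.csr_matrix:
    """Stack binned (and optionally formula) features for a list of spectra."""
    binned = sparse.vstack(
        [bin_spectrum_features(s, bin_width, max_mass) for s in spectra]
    )
    if formulas is None:
        return binned.tocsr()
    if element_order is None or stds is None:
        raise ValueError("element_order and stds required with formulas")
    dense = np.stack(
        [formula_feature_vector(f, element_order, stds) for f in formulas]
    )
    return sparse.hstack([binned, sparse.csr_matrix(dense)]).tocsr()
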