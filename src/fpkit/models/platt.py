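"""Platt calibration: sigmoid mapping of decision values to probabilities."""

from __future__ import annotations

import numpy as np
from scipy import optimize


def platt_targets(labels: np.ndarray) -> np.ndarray:
    """Regularized target values: (N+ + 1)/(N+ + 2) for positives, 1/(N- + 2)
    for negatives. The smoothing avoids fitting to extreme probabilities."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    return np.where(labels == 1, t_pos, t_neg)


def fit_platt(
    decision_values: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Fit sigmoid parameters (A, B) so that p(d) = 1 / (1 + exp(A d + B)).

    Minimizes the weighted cross-entropy against the smoothed targets. For a
    correctly oriented classifier (higher decision value means positive) the
    fitted A is negative, making p monotone increasing in d.

    Raises
    ------
    ValueError
        If only one class is present; callers should substitute a fixed
        prior probability in that case (see :func:`prior_platt_params`).
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if d.shape != y.shape:
        raise ValueError("decision values and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("Platt fitting requires both classes")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    t = platt_targets(y)

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        A, B = params
        z = A * d + B
        # p = sigmoid(-z); NLL = sum w [log(1 + e^z) - (1 - t) z]
        nll = float((w * (np.logaddexp(0.0, z) - (1.0 - t) * z)).sum())
        one_minus_p = np.where(
            z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z))
        )
        dz = w * (one_minus_p - (1.0 - t))
        return nll, np.array([float((dz * d).sum()), float(dz.sum())])

    # Start from the prior-only solution (A=0, B matching the base rate).
    t_mean = float((w * t).sum() / w.sum())
    b0 = np.log((1.0 - t_mean) / t_mean)
    result = optimize.minimize(
        objective, x0=np.array([0.0, b0]), jac=True, method="L-BFGS-B"
    )
    A, B = result.x
    return float(A), float(B)


def prior_platt_params(prior: float) -> tuple[float, float]:
    """Constant-probability parameters for single-class labels: A=0 and B
    chosen so the sigmoid returns ``prior`` for any decision value."""
    prior = min(max(prior, 1e-4), 1.0 - 1e-4)
    return 0.0, float(np.log(1.0 / prior - 1.0))


def platt_probability(
    decision_values: np.ndarray, A: float, B: float
) -> np.ndarray:
    """Apply p(d) = 1 / (1 + exp(A d + B)) elementwise (numerically stable)."""
    z = A * np.asarray(decision_values, dtype=float) + B
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out
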