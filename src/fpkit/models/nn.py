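"""Minimal multi-layer perceptron trained by minibatch gradient descent.

Dense layers with rectified-linear hidden activations and a linear output
layer producing per-label logits. Supports inverted dropout on hidden
activations, l2 regularization on the output layer, per-sample weights,
sigmoid cross-entropy or hinge loss, and plain-SGD or Adam updates. All
randomness (initialization, shuffling, dropout) flows through one seeded
generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

_ADAM_B1 = 0.9
_ADAM_B2 = 0.999
_ADAM_EPS = 1e-8


def _as_dense_rows(X, idx: np.ndarray) -> np.ndarray:
    if sparse.issparse(X):
        return X[idx]
    return np.asarray(X)[idx]


def _matmul(X, W: np.ndarray) -> np.ndarray:
    out = X @ W
    if sparse.issparse(out):  # pragma: no cover - defensive
        out = out.toarray()
    return np.asarray(out)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Feed-forward network: ``layer_dims = [input, hidden..., output]``.

    Hidden weights are initialized scaled-uniform by fan-in; the output
    layer starts at zero, so an untrained network emits logit 0
    (probability 0.5) everywhere.
    """

    def __init__(
        self,
        layer_dims: list[int],
        seed: int = 0,
        dropout_rate: float = 0.0,
        l2_output: float = 0.0,
        loss: str = "sigmoid_cross_entropy",
        svm_C: float = 1.0,
    ) -> None:
        if len(layer_dims) < 2:
            raise ValueError("need at least input and output dimensions")
        if any(d <= 0 for d in layer_dims):
            raise ValueError("all layer dimensions must be positive")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if loss not in ("sigmoid_cross_entropy", "hinge"):
            raise ValueError(f"unknown loss {loss!r}")
        self.layer_dims = list(layer_dims)
        self.dropout_rate = float(dropout_rate)
        self.l2_output = float(l2_output)
        self.loss = loss
        self.svm_C = float(svm_C)
        self._rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for layer, (d_in, d_out) in enumerate(zip(layer_dims[:-1], layer_dims[1:])):
            if layer == len(layer_dims) - 2:
                W = np.zeros((d_in, d_out))
            else:
                bound = np.sqrt(6.0 / d_in)
                W = self._rng.uniform(-bound, bound, size=(d_in, d_out))
            self.weights.append(W)
            self.biases.append(np.zeros(d_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def decision_values(self, X) -> np.ndarray:
        """Forward pass without dropout (inference mode); returns logits."""
        h = X
        for layer in range(self.n_layers - 1):
            h = np.maximum(_matmul(h, self.weights[layer]) + self.biases[layer], 0.0)
        return _matmul(h, self.weights[-1]) + self.biases[-1]

    def _forward_train(self, X, rng: np.random.Generator):
        activations = [X]
        masks = []
        h = X
        for layer in range(self.n_layers - 1):
            h = np.maximum(_matmul(h, self.weights[layer]) + self.biases[layer], 0.0)
            if self.dropout_rate > 0.0:
                mask = (
                    rng.random(h.shape) >= self.dropout_rate
                ) / (1.0 - self.dropout_rate)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            activations.append(h)
        logits = _matmul(h, self.weights[-1]) + self.biases[-1]
        return activations, masks, logits

    def _loss_grad_logits(
        self, logits: np.ndarray, Y: np.ndarray, sw: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Loss value and gradient w.r.t. logits, weighted-mean over samples."""
        wsum = sw.sum()
        if self.loss == "sigmoid_cross_entropy":
            # log(1 + e^z) - y z, numerically stable
            per = np.logaddexp(0.0, logits) - Y * logits
            loss = float((sw[:, None] * per).sum() / wsum)
            grad = sw[:, None] * (sigmoid(logits) - Y) / wsum
        else:  # hinge on y in {-1, +1}
            y_pm = 2.0 * Y - 1.0
            margin = 1.0 - y_pm * logits
            per = np.maximum(margin, 0.0)
            loss = float((sw[:, None] * per).sum() / wsum)
            grad = sw[:, None] * np.where(margin > 0, -y_pm, 0.0) / wsum
        return loss, grad

    def loss_and_grads(
        self,
        X,
        Y: np.ndarray,
        sample_weights: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ):
        """Objective and parameter gradients on one batch.

        Objective = weighted-mean per-sample loss (summed over labels) plus
        the output-layer penalty: ``l2_output * ||W_out||^2`` for the
        cross-entropy loss, or ``||W_out||^2 / (2 C)`` for the hinge loss.
        """
        if not training:
            raise ValueError("loss_and_grads requires training=True")
        sw = np.asarray(sample_weights, dtype=float)
        if rng is None:
            rng = np.random.default_rng(0)
        activations, masks, logits = self._forward_train(X, rng)
        loss, dlogits = self._loss_grad_logits(logits, Y, sw)

        if self.loss == "hinge":
            reg_coeff = 1.0 / self.svm_C
        else:
            reg_coeff = 2.0 * self.l2_output
        W_out = self.weights[-1]
        if self.loss == "hinge":
            loss += float((W_out**2).sum()) / (2.0 * self.svm_C)
        else:
            loss += self.l2_output * float((W_out**2).sum())

        grads_W = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        delta = dlogits
        for layer in range(self.n_layers - 1, -1, -1):
            a = activations[layer]
            if sparse.issparse(a):
                gW = np.asarray((a.T @ delta))
            else:
                gW = a.T @ delta
            if layer == self.n_layers - 1:
                gW = gW + reg_coeff * self.weights[layer]
            grads_W[layer] = gW
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                mask = masks[layer - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (activations[layer] > 0)
        return loss, grads_W, grads_b

    def fit(
        self,
        X,
        Y: np.ndarray,
        sample_weights: np.ndarray | None = None,
        epochs: int = 25,
        batch_size: int = 200,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        seed: int = 0,
        record_loss: bool = False,
    ) -> list[float]:
        """Train in place; returns per-epoch mean batch losses if requested."""
        if optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        n = X.shape[0]
        Y = np.asarray(Y, dtype=float)
        if sample_weights is None:
            sample_weights = np.ones(n)
        sample_weights = np.asarray(sample_weights, dtype=float)
        rng = np.random.default_rng(seed)
        m_W = [np.zeros_like(W) for W in self.weights]
        v_W = [np.zeros_like(W) for W in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        step = 0
        history: list[float] = []
        for _epoch in range(epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                Xb = _as_dense_rows(X, idx)
                loss, gW, gb = self.loss_and_grads(
                    Xb, Y[idx], sample_weights[idx], rng=rng
                )
                batch_losses.append(loss)
                step += 1
                for layer in range(self.n_layers):
                    if optimizer == "sgd":
                        self.weights[layer] -= learning_rate * gW[layer]
                        self.biases[layer] -= learning_rate * gb[layer]
                    else:
                        for param, grad, m, v in (
                            (self.weights[layer], gW[layer], m_W, v_W),
                            (self.biases[layer], gb[layer], m_b, v_b),
                        ):
                            m[layer] = _ADAM_B1 * m[layer] + (1 - _ADAM_B1) * grad
                            v[layer] = _ADAM_B2 * v[layer] + (1 - _ADAM_B2) * grad**2
                            mhat = m[layer] / (1 - _ADAM_B1**step)
                            vhat = v[layer] / (1 - _ADAM_B2**step)
                            param -= learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
            if record_loss:
                history.append(float(np.mean(batch_losses)))
        return history

    def dataset_loss(self, X, Y: np.ndarray, sample_weights: np.ndarray) -> float:
        """Objective on a full dataset without dropout (evaluation mode)."""
        sw = np.asarray(sample_weights, dtype=float)
        logits = self.decision_values(X)
        loss, _ = self._loss_grad_logits(logits, np.asarray(Y, dtype=float), sw)
        W_out = self.weights[-1]
        if self.loss == "hinge":
            loss += float((W_out**2).sum()) / (2.0 * self.svm_C)
        else:
            loss += self.l2_output * float((W_out**2).sum())
        return loss
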