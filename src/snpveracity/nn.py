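"""A small dense feed-forward network in NumPy.

Implements exactly what the classifier needs: fully connected layers with
ReLU hidden activations and a sigmoid head, inverted dropout after chosen
layers, (optionally sample-weighted) binary cross-entropy, and the Adam
update.  Everything is driven by an explicit ``numpy.random.Generator`` so
training is reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(
    p: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> float:
    """Mean of (optionally weighted) per-sample binary cross-entropy."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    per_sample = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if sample_weight is not None:
        per_sample = per_sample * sample_weight
    return float(np.mean(per_sample))


class FeedForwardNet:
    """Dense network: ``n_features -> layer_sizes[0] -> ... -> 1``.

    ``dropout_after_layers`` are 1-based layer numbers after whose
    activation inverted dropout (rate ``dropout_rate``) is applied during
    training.  The last layer uses a sigmoid; all earlier layers use ReLU.
    """

    def __init__(
        self,
        n_features: int,
        layer_sizes: tuple[int, ...],
        dropout_rate: float = 0.2,
        dropout_after_layers: tuple[int, ...] = (1, 2, 3, 4, 5),
        seed: int = 0,
    ):
        self.n_features = int(n_features)
        self.layer_sizes = tuple(layer_sizes)
        self.dropout_rate = float(dropout_rate)
        self.dropout_after_layers = frozenset(dropout_after_layers)
        rng = np.random.default_rng(seed)
        fan_ins = (n_features,) + self.layer_sizes[:-1]
        # He initialization for the ReLU stack
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / fi), size=(fi, fo))
            for fi, fo in zip(fan_ins, self.layer_sizes)
        ]
        self.b = [np.zeros(fo) for fo in self.layer_sizes]
        # Adam state
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward pass.

        Returns ``(outputs, raw, masks)`` where ``outputs[l]`` is the
        post-dropout activation fed to layer ``l`` (``outputs[0]`` is the
        input), ``raw[l]`` the pre-dropout activation of layer ``l+1`` and
        ``masks[l]`` the dropout mask applied to it (None if no dropout).
        """
        a = X
        outputs = [a]
        raw: list[np.ndarray] = []
        masks: list[np.ndarray | None] = []
        keep = 1.0 - self.dropout_rate
        for layer in range(self.n_layers):
            z = a @ self.W[layer] + self.b[layer]
            a = sigmoid(z) if layer == self.n_layers - 1 else np.maximum(z, 0.0)
            raw.append(a)
            mask = None
            if (
                dropout_rng is not None
                and (layer + 1) in self.dropout_after_layers
                and self.dropout_rate > 0.0
            ):
                mask = (dropout_rng.random(a.shape) < keep) / keep
                a = a * mask
            masks.append(mask)
            outputs.append(a)
        return outputs, raw, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        outputs, _, _ = self.forward(np.asarray(X, dtype=float))
        return outputs[-1][:, 0]

    def gradients(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Loss and parameter gradients for one batch.

        The loss is the mean of weighted per-sample binary cross-entropy;
        the sigmoid + BCE combination gives dL/dz = (p - y) * w / n at the
        output pre-activation.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        n = X.shape[0]
        w = (
            np.ones((n, 1))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).reshape(-1, 1)
        )
        outputs, raw, masks = self.forward(X, dropout_rng=dropout_rng)
        p = outputs[-1]
        loss = binary_cross_entropy(p[:, 0], y[:, 0], w[:, 0])

        dW = [np.empty_like(wt) for wt in self.W]
        db = [np.empty_like(bt) for bt in self.b]
        delta = (p - y) * w / n  # dL/dz at the sigmoid head
        for layer in range(self.n_layers - 1, -1, -1):
            dW[layer] = outputs[layer].T @ delta
            db[layer] = delta.sum(axis=0)
            if layer > 0:
                da = delta @ self.W[layer].T
                if masks[layer - 1] is not None:
                    da = da * masks[layer - 1]
                delta = da * (raw[layer - 1] > 0.0)  # ReLU gate on pre-dropout value
        return loss, dW, db

    def adam_step(
        self,
        dW,
        db,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-7,
    ) -> None:
        self._t += 1
        t = self._t
        for layer in range(self.n_layers):
            for g, m, v, param in (
                (dW[layer], self._mW[layer], self._vW[layer], self.W[layer]),
                (db[layer], self._mb[layer], self._vb[layer], self.b[layer]),
            ):
                m *= beta1
                m += (1.0 - beta1) * g
                v *= beta2
                v += (1.0 - beta2) * g * g
                m_hat = m / (1.0 - beta1**t)
                v_hat = v / (1.0 - beta2**t)
                param -= learning_rate * m_hat / (np.sqrt(v_hat) + epsilon)

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights) -> None:
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [bb.copy() for bb in b]
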