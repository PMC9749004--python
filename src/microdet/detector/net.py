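"""Minimal dense layers with hand-derived gradients and Adam updates.

The whole learnable surface of the detector is a handful of dense layers
(the RPN 3x3 convolution is a dense layer over im2col patches), so a few
dozen lines of explicit backprop cover it.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Fully connected layer with its own Adam state."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._m = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._v = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._t = 0
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray, accumulate: bool = False) -> np.ndarray:
        assert self._x is not None
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        if accumulate:
            self.dW += dW
            self.db += db
        else:
            self.dW = dW
            self.db = db
        return dout @ self.W.T

    def step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._t += 1
        for p, g, m, v in (
            (self.W, self.dW, self._m[0], self._v[0]),
            (self.b, self.db, self._m[1], self._v[1]),
        ):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    # -- (de)serialisation --------------------------------------------------

    def state(self) -> dict[str, np.ndarray]:
        return {"W": self.W.copy(), "b": self.b.copy()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.W = state["W"].copy()
        self.b = state["b"].copy()


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Mean cross-entropy, its gradient wrt logits, and the accuracy."""
    n = logits.shape[0]
    if n == 0:
        return 0.0, np.zeros_like(logits), 1.0
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    acc = float((p.argmax(axis=1) == labels).mean())
    return loss, grad, acc


def smooth_l1(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Smooth-L1 (Huber at delta=1) summed over coords, mean over rows."""
    n = pred.shape[0]
    if n == 0:
        return 0.0, np.zeros_like(pred)
    d = pred - target
    ad = np.abs(d)
    quad = ad < 1.0
    loss = float(np.where(quad, 0.5 * d * d, ad - 0.5).sum() / n)
    grad = np.where(quad, d, np.sign(d)) / n
    return loss, grad
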