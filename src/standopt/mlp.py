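"""Minimal feedforward Q-network with manual backpropagation.

Three ReLU hidden layers of 24 units and a linear output head, trained by
stochastic gradient descent on the squared temporal-difference error of
the taken action.  Weights live in plain numpy arrays, which keeps the
learner fully deterministic under a seeded generator and dependency-free.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["QNetwork"]


class QNetwork:
    """Small MLP mapping an observation vector to per-action Q-values."""

    def __init__(self, n_in: int, n_out: int,
                 hidden: tuple[int, ...] = (24, 24, 24),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        sizes = [n_in, *hidden, n_out]
        self.weights = []
        self.biases = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / a)  # He initialisation for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(a, b)))
            self.biases.append(np.zeros(b))
        # zero output head: initial Q == 0 for every action, so the greedy
        # tie-break starts at the first (forward) action instead of a
        # random-net artefact
        self.weights[-1][:] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Q-values for a batch (or single) observation."""
        h = np.atleast_2d(np.asarray(x, dtype=float))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def gradient_step(self, x: np.ndarray, actions: np.ndarray,
                      targets: np.ndarray, lr: float,
                      huber_delta: float = 10.0,
                      max_grad_norm: float = 10.0) -> float:
        """One SGD step on the Huber TD error of the taken actions.

        The Huber form (quadratic within ``huber_delta``, linear beyond)
        plus a global gradient-norm clip keeps bootstrapped targets with
        large reward magnitudes from destabilising plain SGD.  Returns
        the batch loss (used for divergence detection).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = len(x)
        # forward with caches
        activations = [x]
        pre = []
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = h @ w + b
            pre.append(z)
            h = np.maximum(z, 0.0)
            activations.append(h)
        q = h @ self.weights[-1] + self.biases[-1]
        picked = q[np.arange(n), actions]
        err = picked - np.asarray(targets, dtype=float)
        small = np.abs(err) <= huber_delta
        loss = float(np.mean(np.where(
            small, 0.5 * err ** 2,
            huber_delta * (np.abs(err) - 0.5 * huber_delta))))
        # backward: dL/dq only on taken actions, Huber-clipped error
        derr = np.where(small, err, huber_delta * np.sign(err)) / n
        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = derr
        grads_w = []
        grads_b = []
        delta = dq
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(activations[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) \
                    * (pre[layer - 1] > 0.0)
        grads_w.reverse()
        grads_b.reverse()
        norm = math.sqrt(sum(float((g ** 2).sum())
                             for g in grads_w + grads_b))
        scale = 1.0 if norm <= max_grad_norm else max_grad_norm / norm
        for w, b, gw, gb in zip(self.weights, self.biases, grads_w, grads_b):
            w -= lr * scale * gw
            b -= lr * scale * gb
        return loss

    def copy_weights_from(self, other: "QNetwork") -> None:
        self.weights = [w.copy() for w in other.weights]
        self.biases = [b.copy() for b in other.biases]
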