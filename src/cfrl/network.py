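"""A small feed-forward Q-network in plain numpy.

Architecture: rectified-linear hidden layers (default 128/64/32) and a linear
output head with one value per action.  Training follows the Q-learning
rule: for a batch of (state, action, target) triples the parameters move
along ``alpha * mean_i[(target_i - Q(s_i, a_i)) * grad Q(s_i, a_i)]``, which
is gradient descent on half the mean squared temporal-difference error.
Optimizers: plain SGD (exactly the textbook rule) or Adam (default for
training).  Everything is seeded and single-threaded, so runs are
bit-reproducible.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 0.9, 0.999, 1e-8


class QNetwork:
    """MLP mapping a state vector to one Q-value per action."""

    def __init__(
        self,
        n_inputs: int,
        n_actions: int,
        hidden: Sequence[int] = (128, 64, 32),
        seed: int = 0,
        optimizer: str = "adam",
        lr: float = 25e-4,
        use_bias: bool = True,
    ) -> None:
        if optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        self.n_inputs = int(n_inputs)
        self.n_actions = int(n_actions)
        self.hidden = tuple(int(h) for h in hidden)
        self.optimizer = optimizer
        self.lr = float(lr)
        self.use_bias = bool(use_bias)
        rng = np.random.default_rng(seed)
        sizes = [self.n_inputs, *self.hidden, self.n_actions]
        # He initialization suits the rectified-linear hidden layers; the
        # linear value head starts near zero so initial Q-values carry no
        # spurious preference ordering across actions.
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.W[-1] *= 0.01
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._t = 0
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]

    # -- inference ---------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Q-values for a batch of states, shape (batch, n_actions)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.W[-1] + self.b[-1]

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # -- training ----------------------------------------------------------
    def td_step(
        self,
        states: np.ndarray,
        actions: np.ndarray,
        targets: np.ndarray,
        lr: float | None = None,
    ) -> float:
        """One optimizer step on the chosen-action TD errors.

        Returns the mean squared TD error of the batch (before the step).
        """
        lr = self.lr if lr is None else float(lr)
        X = np.atleast_2d(np.asarray(states, dtype=float))
        actions = np.asarray(actions, dtype=int)
        targets = np.asarray(targets, dtype=float)
        batch = X.shape[0]

        activations = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            activations.append(h)
        out = h @ self.W[-1] + self.b[-1]

        chosen = out[np.arange(batch), actions]
        err = chosen - targets  # derivative of 0.5*err^2 is err
        loss = float(np.mean(err**2))

        delta = np.zeros_like(out)
        delta[np.arange(batch), actions] = err / batch
        gW: list[np.ndarray] = [None] * len(self.W)  # type: ignore[list-item]
        gb: list[np.ndarray] = [None] * len(self.b)  # type: ignore[list-item]
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = activations[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (activations[layer] > 0)

        if not self.use_bias:
            gb = [np.zeros_like(g) for g in gb]
        if self.optimizer == "sgd":
            for layer in range(len(self.W)):
                self.W[layer] -= lr * gW[layer]
                self.b[layer] -= lr * gb[layer]
        else:
            self._t += 1
            correct1 = 1.0 - ADAM_BETA1**self._t
            correct2 = 1.0 - ADAM_BETA2**self._t
            for layer in range(len(self.W)):
                for param, grad, m, v in (
                    (self.W[layer], gW[layer], self._mW, self._vW),
                    (self.b[layer], gb[layer], self._mb, self._vb),
                ):
                    m[layer] = ADAM_BETA1 * m[layer] + (1 - ADAM_BETA1) * grad
                    v[layer] = ADAM_BETA2 * v[layer] + (1 - ADAM_BETA2) * grad**2
                    param -= lr * (m[layer] / correct1) / (
                        np.sqrt(v[layer] / correct2) + ADAM_EPS
                    )
        return loss

    # -- utilities ---------------------------------------------------------
    def copy_weights_from(self, other: "QNetwork") -> None:
        for layer in range(len(self.W)):
            self.W[layer][...] = other.W[layer]
            self.b[layer][...] = other.b[layer]

    def clone(self) -> "QNetwork":
        twin = QNetwork(
            self.n_inputs, self.n_actions, self.hidden,
            seed=0, optimizer=self.optimizer, lr=self.lr, use_bias=self.use_bias,
        )
        twin.copy_weights_from(self)
        return twin
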