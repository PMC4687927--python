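"""A small seeded self-organizing (Kohonen) map.

Used only to partition labeled segments into training and validation sets so
that both sets sample every occupied neuron; any reasonable SOM satisfies
that contract.  Rectangular grid, Gaussian neighborhood, linearly decaying
learning rate and radius, online updates in a seed-fixed sample order.
"""

from __future__ import annotations

import numpy as np


class SelfOrganizingMap:
    """Rectangular SOM with Gaussian neighborhood and linear decay."""

    def __init__(
        self,
        n_rows: int,
        n_cols: int,
        dim: int,
        seed: int = 0,
        learning_rate: float = 0.5,
    ) -> None:
        if n_rows * n_cols < 2:
            raise ValueError("SOM must have at least 2 neurons")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.dim = dim
        self.seed = seed
        self.learning_rate = learning_rate
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(size=(n_rows * n_cols, dim))
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        # squared grid distances between all neuron pairs, precomputed
        self._grid_d2 = (rows[:, None] - rows[None, :]) ** 2 + (
            cols[:, None] - cols[None, :]
        ) ** 2

    def fit(self, X: np.ndarray, epochs: int = 10) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.seed)
        # seed weights from data points to start inside the data cloud
        init_idx = rng.choice(len(X), size=self.weights.shape[0], replace=True)
        self.weights = X[init_idx].copy() + rng.normal(
            scale=1e-3, size=self.weights.shape
        )
        n_steps = epochs * len(X)
        radius0 = max(self.n_rows, self.n_cols) / 2.0
        step = 0
        for _ in range(epochs):
            order = rng.permutation(len(X))
            for i in order:
                frac = step / max(n_steps - 1, 1)
                lr = self.learning_rate * (1.0 - frac)
                radius = max(radius0 * (1.0 - frac), 0.5)
                bmu = int(
                    np.argmin(((self.weights - X[i]) ** 2).sum(axis=1))
                )
                h = np.exp(-self._grid_d2[bmu] / (2.0 * radius**2))
                self.weights += (lr * h)[:, None] * (X[i] - self.weights)
                step += 1
        return self

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Index of the best-matching neuron for each row of X."""
        X = np.asarray(X, dtype=float)
        # ||x - w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; ||x||^2 constant per row
        cross = X @ self.weights.T
        w2 = (self.weights**2).sum(axis=1)
        return np.argmin(w2[None, :] - 2.0 * cross, axis=1)
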