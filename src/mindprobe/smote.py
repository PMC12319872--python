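"""Synthetic minority over-sampling (SMOTE) for the training partition.

A synthetic minority sample is x + u * (x_nn - x) with u ~ U(0, 1) and
x_nn drawn among the k nearest minority neighbors of x (k capped at
minority count - 1); samples are added until the class counts are
equal. Applied only to training data — never to validation or test
partitions.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def smote_balance(X: np.ndarray, y: np.ndarray, k: int = 5, seed=None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a binary problem to parity.

    X is (n, n_features); y is binary. Returns the augmented (X, y)
    with synthetic rows appended. Already-balanced input is returned
    unchanged; a minority class with fewer than 2 samples raises
    ValueError.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, n_features) aligned with y")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xmin = X[y == minority]
    m = len(Xmin)
    if m < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k_eff = min(k, m - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, m, size=n_needed)
    pick = rng.integers(0, k_eff, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x0 = Xmin[base]
    x1 = Xmin[neigh[base, pick]]
    synthetic = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out
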