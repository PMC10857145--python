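"""Independent step-by-step reference implementations used as test oracles.

Deliberately written with explicit loops and no shared code with the
package, so agreement is evidence of correctness rather than tautology.
"""
from __future__ import annotations

import math

import numpy as np


def brute_topsis(A, weights, benefit):
    """TOPSIS scores computed literally, step by step.

    A: m x n non-negative raw matrix (list of lists ok);
    weights: length-n, already summing to 1; benefit: length-n booleans.
    """
    A = [list(map(float, row)) for row in A]
    m, n = len(A), len(A[0])
    # step: vector-normalize each column
    R = [[0.0] * n for _ in range(m)]
    for j in range(n):
        norm = math.sqrt(sum(A[i][j] ** 2 for i in range(m)))
        for i in range(m):
            R[i][j] = A[i][j] / norm if norm > 0 else 0.0
    # step: weight
    T = [[R[i][j] * weights[j] for j in range(n)] for i in range(m)]
    # step: ideal best / worst per direction
    best, worst = [0.0] * n, [0.0] * n
    for j in range(n):
        col = [T[i][j] for i in range(m)]
        if benefit[j]:
            best[j], worst[j] = max(col), min(col)
        else:
            best[j], worst[j] = min(col), max(col)
    # step: distances and closeness to the worst
    scores = []
    for i in range(m):
        d_b = math.sqrt(sum((T[i][j] - best[j]) ** 2 for j in range(n)))
        d_w = math.sqrt(sum((T[i][j] - worst[j]) ** 2 for j in range(n)))
        scores.append(d_w / (d_w + d_b) if d_w + d_b > 0 else 0.5)
    return np.array(scores)


def eigen_ahp(pairwise):
    """AHP weights via a full dense eigendecomposition (numpy.linalg.eig)."""
    A = np.asarray(pairwise, dtype=float)
    values, vectors = np.linalg.eig(A)
    principal = np.argmax(values.real)
    w = np.abs(vectors[:, principal].real)
    return w / w.sum(), float(values[principal].real)


def brute_prerow(mu):
    """Deficit-form PV computed longhand on a plain list."""
    mu = [max(float(x), 1e-6) for x in mu]
    i_min = mu.index(min(mu))
    n = len(mu)
    total = 0.0
    for i, x in enumerate(mu):
        if i != i_min:
            total += 1.0 - x
    return min(1.0, max(0.0, mu[i_min] - total / n))
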