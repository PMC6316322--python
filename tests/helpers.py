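"""Independent oracles used by the test suite.

The brute-force maximum-entropy optimizer here deliberately shares no
code with the package's trainer: it maximizes the same penalized
objective by dense grid search over the coefficient vector followed by
coordinate-wise bounded scalar minimization (the objective is concave,
so each 1-D slice is unimodal).  It is only feasible for tiny problems
(<= 3 features, <= ~100 background cells), which is exactly its job.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp


def penalized_objective(F, presence_rows, beta, lam):
    P = F[presence_rows]
    m = len(presence_rows)
    fbar = P.mean(axis=0)
    s = np.maximum(P.std(axis=0) / math.sqrt(m), 1e-6)
    lam = np.asarray(lam, dtype=float)
    return float(fbar @ lam - logsumexp(F @ lam)
                 - beta * (s * np.abs(lam)).sum())


def brute_force_fit(F, presence_rows, beta, span=8.0, coarse=9, passes=80):
    """Penalized-objective maximizer: dense lambda grid + 1-D refinement."""
    K = F.shape[1]
    axis = np.linspace(-span, span, coarse)
    best, best_val = None, -np.inf
    for lam in product(axis, repeat=K):
        v = penalized_objective(F, presence_rows, beta, lam)
        if v > best_val:
            best, best_val = np.array(lam), v
    lam = best.astype(float)
    width = float(axis[1] - axis[0])
    for _ in range(passes):
        moved = 0.0
        for j in range(K):
            def neg(t, j=j):
                trial = lam.copy()
                trial[j] = t
                return -penalized_objective(F, presence_rows, beta, trial)
            res = minimize_scalar(neg, bounds=(lam[j] - width, lam[j] + width),
                                  method="bounded",
                                  options={"xatol": 1e-12})
            moved = max(moved, abs(res.x - lam[j]))
            lam[j] = res.x
        # allow |0| to be hit exactly: the L1 kink attracts coordinates
        for j in range(K):
            zero = lam.copy()
            zero[j] = 0.0
            if (penalized_objective(F, presence_rows, beta, zero)
                    >= penalized_objective(F, presence_rows, beta, lam)):
                lam[j] = 0.0
        if moved < 1e-11:
            break
    eta = F @ lam
    q = np.exp(eta - logsumexp(eta))
    return lam, q


def random_tiny_problem(rng, max_features=3, max_cells=100):
    """A seeded small presence/background problem with a [0,1] design."""
    n = int(rng.integers(10, max_cells + 1))
    k = int(rng.integers(1, max_features + 1))
    F = rng.random((n, k))
    # rescale columns to exactly [0, 1] like the package's feature builder
    F = (F - F.min(axis=0)) / (F.max(axis=0) - F.min(axis=0))
    m = int(rng.integers(3, 21))
    rows = rng.integers(0, n, size=m)
    return F, rows
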