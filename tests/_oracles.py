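"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from its definition with naive
loops, staying independent of the vectorized/graph-based code paths they
check.
"""

from __future__ import annotations

import numpy as np


def components_by_transitive_closure(corr: np.ndarray, threshold: float) -> list[set[int]]:
    """Connected components via brute-force transitive closure on |r| > threshold."""
    m = corr.shape[0]
    adj = np.abs(corr) > threshold
    np.fill_diagonal(adj, True)
    reach = adj.copy()
    for _ in range(m):  # Floyd-Warshall-style closure
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    comps: list[set[int]] = []
    seen: set[int] = set()
    for i in range(m):
        if i in seen:
            continue
        comp = {j for j in range(m) if reach[i, j]}
        comps.append(comp)
        seen |= comp
    return comps


def gower_loop(xi, xj, ranges) -> float:
    """Per-marker loop over the Gower definition."""
    num = den = 0.0
    for a, b, r in zip(xi, xj, ranges):
        valid = (a >= 0) and (b >= 0) and (r > 0)
        if valid:
            num += abs(float(a) - float(b)) / r
            den += 1.0
    if den == 0:
        raise ValueError("no valid marker")
    return num / den


def jaccard_loop(xi, xj) -> float:
    """Per-marker loop over the Jaccard definition."""
    matches = active = 0
    for a, b in zip(xi, xj):
        if a == 0 and b == 0:
            continue
        active += 1
        if a == b:
            matches += 1
    if active == 0:
        raise ValueError("undefined")
    return 1.0 - matches / active


def rf_oob_importance_naive(forest, X, y, perm) -> np.ndarray:
    """Permute-and-score loop over the OOB permutation-importance definition.

    For each feature, permute its column with the given permutation,
    recompute every sample's out-of-bag prediction by looping over trees,
    and report the increase in OOB mean squared error.
    """
    n, m = X.shape
    T = len(forest.estimators_)
    oob = np.ones((n, T), dtype=bool)
    for t, inbag in enumerate(forest.estimators_samples_):
        oob[inbag, t] = False

    def oob_mse(Xq):
        yhat = np.zeros(n)
        counts = np.zeros(n)
        for t, tree in enumerate(forest.estimators_):
            pred = tree.predict(Xq)
            for i in range(n):
                if oob[i, t]:
                    yhat[i] += pred[i]
                    counts[i] += 1
        ok = counts > 0
        return np.mean((y[ok] - yhat[ok] / counts[ok]) ** 2)

    base = oob_mse(X)
    out = np.zeros(m)
    for j in range(m):
        Xp = X.copy()
        Xp[:, j] = Xp[perm, j]
        out[j] = oob_mse(Xp) - base
    return out
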