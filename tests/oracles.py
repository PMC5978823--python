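"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness by
exhaustive simple-path enumeration, modularity by direct double-sum
evaluation, and the LASSO single-predictor closed form.
"""

from itertools import permutations

import numpy as np


def betweenness_bruteforce(W: np.ndarray) -> np.ndarray:
    """Directed weighted betweenness by enumerating every simple path.

    Edge cost is 1/|w|; for each ordered pair (s, t) all simple paths are
    enumerated, the minimum total cost found, and each intermediate node of
    every co-minimal path credited 1/#co-minimal paths.
    """
    p = W.shape[0]
    cost = np.full((p, p), np.inf)
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] != 0:
                cost[i, j] = 1.0 / abs(W[i, j])
    score = np.zeros(p)
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best, minimal_paths = np.inf, []
            # enumerate simple paths s -> t by choosing intermediate subsets
            others = [v for v in range(p) if v not in (s, t)]
            for r in range(len(others) + 1):
                for mids in permutations(others, r):
                    path = (s, *mids, t)
                    c = sum(cost[path[k], path[k + 1]] for k in range(len(path) - 1))
                    if c < best:
                        best, minimal_paths = c, [path]
                    elif c == best and np.isfinite(c):
                        minimal_paths.append(path)
            if not np.isfinite(best):
                continue
            sigma = len(minimal_paths)
            for path in minimal_paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / sigma
    return score


def modularity_direct(W: np.ndarray, labels: np.ndarray) -> float:
    """Signed directed modularity by literal evaluation of the double sum."""
    Q = 0.0
    p = W.shape[0]
    for sign in (1.0, -1.0):
        w = np.where(sign * W > 0, sign * W, 0.0)
        m = w.sum()
        if m == 0:
            continue
        sout = w.sum(axis=1)
        sin = w.sum(axis=0)
        q = 0.0
        for i in range(p):
            for j in range(p):
                if labels[i] == labels[j]:
                    q += w[i, j] - sout[i] * sin[j] / m
        Q += sign * q / m
    return Q


def soft_threshold(r: float, lam: float) -> float:
    """Closed-form LASSO solution for one standardized predictor."""
    return float(np.sign(r) * max(abs(r) - lam, 0.0))


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normal-equations least squares (no intercept)."""
    return np.linalg.solve(X.T @ X, X.T @ y)
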