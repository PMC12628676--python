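"""Independent brute-force oracles used to check the package's fast paths.

These deliberately share no code with the implementation: plain double loops
over taxa, no vectorization, no caching.
"""

from __future__ import annotations

import numpy as np


def brute_force_beta_mntd(counts_k, counts_m, dist, weighted=True):
    """betaMNTD between two count vectors by explicit double loops.

    ``dist`` is the taxa x taxa cophenetic matrix aligned with the vectors.
    """
    counts_k = np.asarray(counts_k, dtype=float)
    counts_m = np.asarray(counts_m, dtype=float)
    present_k = [i for i in range(len(counts_k)) if counts_k[i] > 0]
    present_m = [j for j in range(len(counts_m)) if counts_m[j] > 0]
    if not present_k or not present_m:
        raise ValueError("empty community")

    def half(present_a, counts_a, present_b):
        total = counts_a.sum() if weighted else float(len(present_a))
        acc = 0.0
        for i in present_a:
            best = min(dist[i][j] for j in present_b)
            f = counts_a[i] / total if weighted else 1.0 / total
            acc += f * best
        return acc

    return 0.5 * (half(present_k, counts_k, present_m) + half(present_m, counts_m, present_k))


def brute_force_permanova_ss(points, groups):
    """SS decomposition for Euclidean points via explicit centroid sums."""
    points = np.asarray(points, dtype=float)
    groups = np.asarray(groups)
    grand = points.mean(axis=0)
    ss_total = float(((points - grand) ** 2).sum())
    ss_within = 0.0
    for g in set(groups.tolist()):
        sub = points[groups == g]
        ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return ss_total, ss_within


def normal_equation_ols(x, y):
    """Slope and intercept by solving the normal equations directly."""
    X = np.column_stack([np.ones(len(x)), np.asarray(x, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    return float(beta[1]), float(beta[0])
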