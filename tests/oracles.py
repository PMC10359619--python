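"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (nested loops, exact integer
arithmetic, dense eigendecompositions) and written without reference to
the library code paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np


def tom_brute_force(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of a symmetric adjacency."""
    n = adj.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = 0.0
            for u in range(n):
                if u != i and u != j:
                    L += adj[i, u] * adj[u, j]
            k_i = sum(adj[i, u] for u in range(n) if u != i)
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            tom[i, j] = (L + adj[i, j]) / (min(k_i, k_j) + 1.0 - adj[i, j])
    return tom


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact integer summation."""
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(max(k, max(0, n - (N - K))), hi + 1))
    return num / comb(N, n)


def average_linkage_naive(diss: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) step-by-step average-linkage agglomeration.

    Returns the merge sequence as (cluster_a, cluster_b, height) with
    clusters given as frozensets of leaf indices. Inter-cluster
    distance is the mean of all pairwise leaf dissimilarities.
    """
    n = diss.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean([diss[a, b] for a in clusters[i] for b in clusters[j]])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return merges


def cophenetic_from_merges(merges, n: int) -> np.ndarray:
    """Cophenetic distance matrix implied by a naive merge sequence."""
    coph = np.zeros((n, n))
    for a_set, b_set, h in merges:
        for a in a_set:
            for b in b_set:
                coph[a, b] = coph[b, a] = h
    return coph


def leading_eigenvector_oracle(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigengene via dense eigendecomposition of the feature covariance.

    X must already be standardized (features zero-mean, unit-variance).
    Returns the sample scores along the leading eigenvector, scaled to
    unit sample variance, and the variance-explained fraction.
    """
    n = X.shape[0]
    cov = X.T @ X / (n - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scores = X @ V[:, 0]
    scores = scores / scores.std(ddof=1)
    return scores, float(w[0] / w.sum())


def ari_pair_counting(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index by exhaustive pair enumeration."""
    n = len(labels_a)
    same_a = same_b = same_both = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            sa = labels_a[i] == labels_a[j]
            sb = labels_b[i] == labels_b[j]
            same_a += sa
            same_b += sb
            same_both += sa and sb
    expected = same_a * same_b / total
    maximum = (same_a + same_b) / 2.0
    if maximum == expected:
        return 1.0 if same_both == expected else 0.0
    return (same_both - expected) / (maximum - expected)


def t_sf_numeric(t: float, df: int) -> float:
    """Upper-tail probability of Student's t by numeric integration."""
    from math import lgamma

    from scipy.integrate import quad

    def density(x: float) -> float:
        logc = lgamma((df + 1) / 2) - lgamma(df / 2) - 0.5 * np.log(df * np.pi)
        return float(np.exp(logc) * (1 + x * x / df) ** (-(df + 1) / 2))

    val, _ = quad(density, t, np.inf)
    return val
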