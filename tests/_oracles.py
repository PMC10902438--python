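"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: affine-gap
alignment by explicit Gotoh dynamic programming, Benjamini-Hochberg by its
step-up definition, and graph clustering by Boolean transitive closure.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def affine_dp_score(
    a: str,
    b: str,
    matrix,
    open_cost: float = 12.0,
    extend_cost: float = 1.0,
    mode: str = "global_free",
) -> float:
    """Best affine-gap alignment score by explicit Gotoh DP.

    Gap of length L costs open_cost + (L - 1) * extend_cost (the first gap
    position carries the opening charge).  ``global_free`` leaves terminal
    gaps unpenalised; ``local`` is Smith-Waterman.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a residue over '-')
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    local = mode == "local"
    best_local = 0.0
    # begin[i][j]: alignment may start here with no charge
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if i > 0 and j > 0:
                s = matrix[a[i - 1], b[j - 1]]
                start_ok = local or i - 1 == 0 or j - 1 == 0
                prev = max(
                    M[i - 1, j - 1],
                    X[i - 1, j - 1],
                    Y[i - 1, j - 1],
                    0.0 if start_ok else NEG,
                )
                M[i, j] = s + prev
                if local:
                    M[i, j] = max(M[i, j], 0.0)
                    best_local = max(best_local, M[i, j])
            if i > 0:
                X[i, j] = max(
                    M[i - 1, j] - open_cost,
                    X[i - 1, j] - extend_cost,
                    Y[i - 1, j] - open_cost,
                )
            if j > 0:
                Y[i, j] = max(
                    M[i, j - 1] - open_cost,
                    X[i, j - 1] - open_cost,
                    Y[i, j - 1] - extend_cost,
                )
    if local:
        return best_local
    # free terminal gaps: end anywhere on the last row or column
    best = 0.0
    for i in range(n + 1):
        best = max(best, M[i, m], X[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j], Y[n, j])
    return best


def bh_stepup(pvalues) -> np.ndarray:
    """BH adjusted values straight from the definition: q(i) = min_{j>=i} m p(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def closure_components(adjacency: np.ndarray) -> list[list[int]]:
    """Connected components via Boolean transitive closure (Warshall)."""
    reach = adjacency.astype(bool).copy()
    np.fill_diagonal(reach, True)
    n = reach.shape[0]
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = sorted(np.where(reach[i])[0].tolist())
        seen.update(comp)
        comps.append(comp)
    return comps
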