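"""Independent brute-force oracles kept deliberately naive.

These never share code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_search_r(
    schedule: dict[int, float], lo: float, hi: float, step: float = 1e-6
) -> float:
    """Minimize |sum(exp(-r (x+1)) phi_x) - 1| over an r grid."""
    ages = np.array(sorted(schedule), dtype=float)
    phi = np.array([schedule[int(x)] for x in ages])
    grid = np.arange(lo, hi, step)
    lhs = np.exp(-np.outer(grid, ages + 1.0)) @ phi
    return float(grid[np.argmin(np.abs(lhs - 1.0))])


def leslie_growth_factor(lx: np.ndarray, mx: np.ndarray) -> float:
    """Asymptotic growth factor of the daily age-classified projection.

    First-row fertilities are m_x, subdiagonal survivals l_{x+1}/l_x,
    truncated at the last age with survivors; the dominant eigenvalue of
    this matrix solves sum(l_x m_x lam^-(x+1)) = 1.
    """
    alive = np.nonzero(lx > 0)[0]
    last = alive[-1]
    k = last + 1
    A = np.zeros((k, k))
    A[0, :] = mx[:k]
    for x in range(k - 1):
        A[x + 1, x] = lx[x + 1] / lx[x]
    eig = np.linalg.eigvals(A)
    return float(np.max(np.abs(eig)))


def exhaustive_mean_sd(values: list[float]) -> float:
    """SD (ddof=0) of the sample mean over all n^n ordered resamples."""
    n = len(values)
    means = [
        float(np.mean([values[i] for i in combo]))
        for combo in itertools.product(range(n), repeat=n)
    ]
    return float(np.std(means, ddof=0))
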