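"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's computational paths (closed-form
blocks, vectorization, library shortcuts): plain loops, dense matrices and
textbook formulas, so agreement is a meaningful cross-check.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy.optimize import minimize_scalar


# -- geNorm ----------------------------------------------------------------

def genorm_m_bruteforce(matrix: np.ndarray) -> list[float]:
    """Stability M per protein: mean over partners of SD of pairwise log2 ratios."""
    p, _ = matrix.shape
    m = []
    for j in range(p):
        vs = []
        for k in range(p):
            if k == j:
                continue
            ratios = [math.log2(matrix[j, i] / matrix[k, i])
                      for i in range(matrix.shape[1])]
            vs.append(statistics.stdev(ratios))
        m.append(sum(vs) / len(vs))
    return m


def genorm_normalize_bruteforce(
    matrix: np.ndarray, v_threshold: float = 0.15, floor: int = 3, cap: int = 10
) -> np.ndarray:
    """Reference normalization a'_ij = a_ij / NF_i with stepwise reference choice."""
    p, s = matrix.shape
    m = genorm_m_bruteforce(matrix)
    order = sorted(range(p), key=lambda j: (m[j], j))

    def log_nf(n):
        return [sum(math.log2(matrix[order[r], i]) for r in range(n)) / n
                for i in range(s)]

    cap_eff = min(cap, p)
    floor_eff = min(floor, cap_eff)
    n_ref = cap_eff
    for n in range(floor_eff, cap_eff):
        a, b = log_nf(n), log_nf(n + 1)
        v = statistics.stdev([a[i] - b[i] for i in range(s)])
        if v < v_threshold:
            n_ref = n
            break
    nf = [2.0 ** v for v in log_nf(n_ref)]
    out = np.empty_like(matrix, dtype=float)
    for j in range(p):
        for i in range(s):
            out[j, i] = matrix[j, i] / nf[i]
    return out


# -- Benjamini-Hochberg ----------------------------------------------------

def bh_bruteforce(p: list[float]) -> list[float]:
    """Step-up adjusted p-values straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, p[i] * m / (rank + 1))
        adj[i] = min(running_min, 1.0)
    return adj


# -- random-intercept ML likelihood ---------------------------------------

def lmm_loglik_dense(y: np.ndarray, X: np.ndarray, subject: np.ndarray,
                     lam: float) -> float:
    """Profile log-likelihood via the dense N x N marginal covariance."""
    n = len(y)
    subj_ids = {s: k for k, s in enumerate(dict.fromkeys(subject))}
    Z = np.zeros((n, len(subj_ids)))
    for row, s in enumerate(subject):
        Z[row, subj_ids[s]] = 1.0
    V = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    rss = float(r @ Vi @ r)
    sigma2 = rss / n
    _, logdet = np.linalg.slogdet(V)
    return float(-0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n)


def lmm_ml_bruteforce(y: np.ndarray, X: np.ndarray, subject: np.ndarray) -> float:
    """Maximized ML log-likelihood by grid search plus 1-D refinement."""
    lams = [0.0] + list(np.logspace(-6, 4, 121))
    lls = [lmm_loglik_dense(y, X, subject, lam) for lam in lams]
    j = int(np.argmax(lls))
    lo = lams[max(j - 1, 0)]
    hi = lams[min(j + 1, len(lams) - 1)]
    res = minimize_scalar(
        lambda lam: -lmm_loglik_dense(y, X, subject, lam),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(max(-res.fun, lls[j]))
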