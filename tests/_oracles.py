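"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the graphical-lasso oracle
solves the box-constrained dual with a generic quasi-Newton optimizer instead
of coordinate descent, the chi-square oracle computes Pearson's statistic from
expected counts by hand, and the random-correlation factory only uses dense
linear algebra.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def random_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    """A random full-rank correlation matrix from Wishart-style factors."""
    a = rng.standard_normal((p, 2 * p))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def glasso_oracle(r: np.ndarray, lam: float) -> np.ndarray:
    """Graphical-lasso solution via direct convex optimization of the dual.

    The penalized-likelihood maximizer argmax logdet(T) - tr(RT) - lam*sum|T_ij|
    equals W^{-1} where W maximizes logdet(W) subject to the box constraints
    |W_ij - R_ij| <= lam (off-diagonal) and W_ii = R_ii. The box-constrained
    smooth problem is solved with L-BFGS-B and an analytic gradient, entirely
    independent of any coordinate-descent solver.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if lam == 0:
        return np.linalg.inv(r)
    iu = np.triu_indices(p, k=1)
    diag = np.diag(r).copy()

    def build(x: np.ndarray) -> np.ndarray:
        w = np.zeros((p, p))
        w[iu] = x
        w = w + w.T
        w[np.diag_indices(p)] = diag
        return w

    def fg(x: np.ndarray):
        w_mat = build(x)
        evals, evecs = np.linalg.eigh(w_mat)
        if evals[0] < 1e-10:
            # outside the PD cone: steep linear pull back toward feasibility
            v0 = evecs[:, 0]
            grad = -2.0e6 * np.outer(v0, v0)[iu]
            return 1.0e6 * (1e-10 - evals[0]) + 1.0e6, grad
        winv = (evecs / evals) @ evecs.T
        return -float(np.log(evals).sum()), -2.0 * winv[iu]

    bounds = [(rv - lam, rv + lam) for rv in r[iu]]
    res = minimize(fg, r[iu], jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12})
    return np.linalg.inv(build(res.x))


def pearson_chi2_2x2(n1: int, k1: int, n2: int, k2: int) -> float:
    """Pearson chi-square on the 2x2 table from first principles."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())


def modularity_by_formula(edges, membership, degrees=None) -> float:
    """Weighted modularity straight from its definition over an edge list.

    ``edges`` is an iterable of (u, v, w); each undirected edge is listed once.
    """
    m = sum(w for _, _, w in edges)
    if m == 0:
        return 0.0
    deg: dict = {}
    for u, v, w in edges:
        deg[u] = deg.get(u, 0.0) + w
        deg[v] = deg.get(v, 0.0) + w
    within = sum(w for u, v, w in edges if membership[u] == membership[v])
    comm_deg: dict = {}
    for node, c in membership.items():
        comm_deg[c] = comm_deg.get(c, 0.0) + deg.get(node, 0.0)
    return within / m - sum(d * d for d in comm_deg.values()) / (4.0 * m * m)
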