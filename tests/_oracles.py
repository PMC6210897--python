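"""Independent brute-force oracles for the DEA tests.

Both slacks-based programs are minimized directly in their fractional
form, with no Charnes-Cooper transformation: a lattice search over the
peer-weight simplex with contraction toward the incumbent, combined with
exhaustive enumeration of the basic feasible solutions (vertices) of the
constraint polyhedron. A linear-fractional objective with positive
denominator attains its minimum at a vertex, so on the tiny instances
used in tests the enumeration is exact; the lattice search supplies an
independent upper bound and covers the piecewise reduced objective of
the super-efficiency program. Nothing here touches the LP formulation
under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def simplex_grid(n: int, K: int) -> np.ndarray:
    """All lattice points with coordinates i/K, i >= 0, summing to 1."""
    pts = []
    for bars in combinations(range(K + n - 1), n - 1):
        prev = -1
        comp = []
        for b in bars:
            comp.append(b - prev - 1)
            prev = b
        comp.append(K + n - 2 - prev)
        pts.append(comp)
    return np.asarray(pts, dtype=float) / K


def _sbm_objective(X, Y, k, lam):
    """ρ(λ) for a batch of weights; inf where slack signs are infeasible."""
    x0, y0 = X[k], Y[k]
    s_in = x0 - lam @ X    # must be >= 0
    s_out = lam @ Y - y0   # must be >= 0
    feas = (s_in >= -1e-12).all(axis=1) & (s_out >= -1e-12).all(axis=1)
    num = 1.0 - np.mean(np.maximum(s_in, 0.0) / x0, axis=1)
    den = 1.0 + np.mean(np.maximum(s_out, 0.0) / y0, axis=1)
    rho = np.where(feas, num / den, np.inf)
    return rho


def _super_objective(X, Y, k, lam):
    """δ(λ) with the optimal projection for each λ substituted in."""
    x0, y0 = X[k], Y[k]
    others = [j for j in range(X.shape[0]) if j != k]
    xbar = np.maximum(lam @ X[others], x0)
    ybar = np.minimum(lam @ Y[others], y0)
    num = np.mean(xbar / x0, axis=1)
    den = np.mean(ybar / y0, axis=1)
    return num / den


def _grid_minimize(obj, n_weights: int, K: int = 24, base_K: int = 12,
                   alpha_min: float = 1e-8, max_iter: int = 400) -> float:
    """Pattern search over the simplex: candidates are the coarse lattice
    contracted toward the incumbent; the contraction halves only when no
    candidate improves, so boundary-following descents are not cut off."""
    lam = simplex_grid(n_weights, K)
    vals = obj(lam)
    best = np.argmin(vals)
    best_val, center = vals[best], lam[best]
    if not np.isfinite(best_val):
        raise RuntimeError("no feasible lattice point found")
    base = simplex_grid(n_weights, base_K)
    alpha = 0.5
    for _ in range(max_iter):
        if alpha < alpha_min:
            break
        cand = (1.0 - alpha) * center + alpha * base
        vals = obj(cand)
        i = np.argmin(vals)
        if vals[i] < best_val - 1e-15:
            best_val, center = vals[i], cand[i]
        else:
            alpha *= 0.5
    return float(best_val)


_FEAS_TOL = 1e-9


def _enumerate_vertices(A_eq, b_eq, G, h):
    """All basic feasible solutions of {v : A_eq v = b_eq, G v >= h}.

    Every vertex is determined by dim(v) active constraints; the
    equalities are always active and the remainder are drawn from G.
    """
    dim = A_eq.shape[1]
    n_eq = A_eq.shape[0]
    need = dim - n_eq
    verts = []
    for rows in combinations(range(G.shape[0]), need):
        M = np.vstack([A_eq, G[list(rows)]])
        rhs = np.concatenate([b_eq, h[list(rows)]])
        try:
            v = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            continue
        if (G @ v >= h - _FEAS_TOL).all():
            verts.append(v)
    return verts


def _sbm_vertex_min(X, Y, k: int) -> float:
    """Exact fractional SBM optimum by enumerating the vertices of the
    feasible peer-weight polytope (linear-fractional objectives attain
    their optimum at a vertex)."""
    n = X.shape[0]
    x0, y0 = X[k], Y[k]
    # inequalities on lambda: lam >= 0; x0 - X'lam >= 0; Y'lam - y0 >= 0
    G = np.vstack([np.eye(n), -X.T, Y.T])
    h = np.concatenate([np.zeros(n), -x0, y0])
    A_eq = np.ones((1, n))
    b_eq = np.array([1.0])
    best = np.inf
    for lam in _enumerate_vertices(A_eq, b_eq, G, h):
        val = _sbm_objective(X, Y, k, lam.reshape(1, -1))[0]
        best = min(best, val)
    return best


def _super_vertex_min(X, Y, k: int) -> float:
    """Exact fractional super-efficiency optimum by vertex enumeration in
    the full (lambda, xbar, ybar) space."""
    x0, y0 = X[k], Y[k]
    others = [j for j in range(X.shape[0]) if j != k]
    Xo, Yo = X[others], Y[others]
    p, m, s = Xo.shape[0], X.shape[1], Y.shape[1]
    dim = p + m + s
    Ip, Im, Is = np.eye(p), np.eye(m), np.eye(s)
    Zpm, Zps = np.zeros((p, m)), np.zeros((p, s))
    rows = [
        np.hstack([Ip, Zpm, Zps]),                            # lam >= 0
        np.hstack([-Xo.T, Im, np.zeros((m, s))]),             # xbar >= X'lam
        np.hstack([np.zeros((m, p)), Im, np.zeros((m, s))]),  # xbar >= x0
        np.hstack([Yo.T, np.zeros((s, m)), -Is]),             # ybar <= Y'lam
        np.hstack([np.zeros((s, p + m)), -Is]),               # ybar <= y0
        np.hstack([np.zeros((s, p + m)), Is]),                # ybar >= 0
    ]
    G = np.vstack(rows)
    h = np.concatenate([np.zeros(p), np.zeros(m), x0,
                        np.zeros(s), -y0, np.zeros(s)])
    A_eq = np.hstack([np.ones((1, p)), np.zeros((1, m + s))])
    b_eq = np.array([1.0])
    best = np.inf
    for v in _enumerate_vertices(A_eq, b_eq, G, h):
        xbar, ybar = v[p:p + m], v[p + m:]
        den = np.mean(ybar / y0)
        if den <= 1e-12:
            continue
        best = min(best, float(np.mean(xbar / x0) / den))
    assert dim == G.shape[1]
    return best


def sbm_score_oracle(X, Y, k: int, **kw) -> float:
    """Brute-force VRS SBM score of unit k (vertex enumeration, with the
    lattice search as an independent upper-bound cross-check)."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    grid = _grid_minimize(lambda lam: _sbm_objective(X, Y, k, lam),
                          X.shape[0], **kw)
    exact = _sbm_vertex_min(X, Y, k)
    assert grid >= exact - 1e-7  # lattice points are feasible: upper bound
    return min(grid, exact)


def super_score_oracle(X, Y, k: int, **kw) -> float:
    """Brute-force VRS super-efficiency SBM score of unit k."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    grid = _grid_minimize(lambda lam: _super_objective(X, Y, k, lam),
                          X.shape[0] - 1, **kw)
    exact = _super_vertex_min(X, Y, k)
    assert grid >= exact - 1e-7
    return min(grid, exact)


def random_instance(rng: np.random.Generator, n_max: int = 5,
                    ms_max: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Small strictly-positive DEA instance with n <= n_max, m+s <= ms_max."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, ms_max))
    s = int(rng.integers(1, ms_max - m + 1))
    X = rng.lognormal(0.0, 0.5, size=(n, m))
    Y = rng.lognormal(0.0, 0.5, size=(n, s))
    return X, Y
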