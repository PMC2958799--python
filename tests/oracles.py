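"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a method unrelated to the package's
implementation path: naive double loops for moment matrices, power
iteration with deflation for eigenpairs, and a linear-programming search
over discretized unimodal CDFs for the dip statistic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def covariance_bruteforce(S: np.ndarray) -> np.ndarray:
    """(1/(N-1)) sum (s-A)(s-A)^T via an explicit double loop."""
    N, M = S.shape
    A = np.zeros(M)
    for i in range(N):
        A += S[i]
    A /= N
    C = np.zeros((M, M))
    for i in range(N):
        d = S[i] - A
        for j in range(M):
            for k in range(M):
                C[j, k] += d[j] * d[k]
    return C / (N - 1)


def noncentered_bruteforce(S: np.ndarray) -> np.ndarray:
    N, M = S.shape
    out = np.zeros((M, M))
    for i in range(N):
        for j in range(M):
            for k in range(M):
                out[j, k] += S[i, j] * S[i, k]
    return out / N


def power_iteration_spectrum(A: np.ndarray, tol: float = 1e-12, iters: int = 20000):
    """All eigenpairs of a symmetric matrix by power iteration + deflation."""
    A = A.copy().astype(float)
    M = A.shape[0]
    vals, vecs = [], []
    rng = np.random.default_rng(12345)
    for _ in range(M):
        v = rng.standard_normal(M)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(iters):
            w = A @ v
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                break
            w /= nw
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        lam = float(v @ A @ v)
        vals.append(lam)
        vecs.append(v)
        A -= lam * np.outer(v, v)
    # power iteration converges to the eigenvalue largest in |.|; sort by value
    order = np.argsort(vals)[::-1]
    return np.array(vals)[order], np.column_stack([vecs[i] for i in order])


def dip_lp_oracle(samples: np.ndarray, n_grid_per_gap: int = 6) -> float:
    """Dip statistic by LP minimization over discretized unimodal CDFs.

    For every candidate mode position on a refined grid, solves
    ``min d`` subject to: G piecewise linear on the grid, convex before the
    mode, concave after, within d of the empirical CDF everywhere, rising
    from 0 to 1 (enforced through distant anchor points), with a jump
    allowed only at the mode.  The dip is the minimum over modes, floored
    at 1/(2n) to match the convention that a point mass still counts as a
    half-jump misfit.
    """
    x = np.sort(np.asarray(samples, float))
    n = x.size
    ys, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n  # F at each unique value
    K = ys.size
    if K == 1:
        return 1.0 / (2 * n)
    span = ys[-1] - ys[0]
    big = 1e7 * (span + 1.0)

    # grid: unique values plus interior points in each gap
    grid = [ys[0]]
    kinds = [0]  # index into ys if sample point else -1
    for j in range(K - 1):
        for t in np.linspace(ys[j], ys[j + 1], n_grid_per_gap + 2)[1:-1]:
            grid.append(t)
            kinds.append(-(j + 1))  # interior of interval j (F = cum[j])
        grid.append(ys[j + 1])
        kinds.append(j + 1)
    grid = np.array(grid)
    G = grid.size

    def fval_below(i: int) -> float:
        """F just left of grid point i."""
        k = kinds[i]
        if k >= 0:
            return cum[k - 1] if k > 0 else 0.0
        return cum[-k - 1]

    def fval_at(i: int) -> float:
        k = kinds[i]
        if k >= 0:
            return cum[k]
        return cum[-k - 1]

    best = np.inf
    xs_full = np.concatenate([[ys[0] - big], grid, [ys[-1] + big]])
    for m in range(G):
        # variables: g_0..g_{G-1} (value at each grid point; at the mode this
        # is the post-jump value), a (pre-jump value at the mode), d
        nv = G + 2
        ia, id_ = G, G + 1
        A_ub, b_ub = [], []

        def leq(coefs: dict, rhs: float) -> None:
            row = np.zeros(nv)
            for k, v in coefs.items():
                row[k] = v
            A_ub.append(row)
            b_ub.append(rhs)

        # band constraints: g_i >= F(t_i) - d ; left-limit <= F(t_i^-) + d
        for i in range(G):
            if i == m:
                leq({ia: 1, id_: -1}, fval_below(i))      # a <= F^- + d
                leq({i: 1, id_: -1}, fval_at(i))          # b <= F + d
                leq({i: -1, id_: -1}, -fval_at(i))        # b >= F - d
                leq({ia: 1, i: -1}, 0.0)                  # a <= b
            else:
                leq({i: -1, id_: -1}, -fval_at(i))        # g >= F - d
                leq({i: 1, id_: -1}, fval_below(i))       # g <= F^- + d
            leq({i: 1}, 1.0)
            leq({i: -1}, 0.0)
        if m > 0:
            leq({ia: 1}, 1.0)
            leq({ia: -1}, 0.0)
            leq({m - 1: 1, ia: -1}, 0.0)  # monotone into the mode
        else:
            leq({ia: 1}, 1.0)
            leq({ia: -1}, 0.0)
        # piecewise-linear left piece through (anchor, 0), grid[:m], (t_m, a)
        left_pts = [(xs_full[0], None)] + [(grid[i], i) for i in range(m)] + [
            (grid[m], ia)
        ]
        for j in range(len(left_pts) - 2):
            (x0, v0), (x1, v1), (x2, v2) = left_pts[j], left_pts[j + 1], left_pts[j + 2]
            # slope(x0,x1) <= slope(x1,x2): (g1-g0)(x2-x1) <= (g2-g1)(x1-x0)
            co = {}
            if v0 is not None:
                co[v0] = co.get(v0, 0) - (x2 - x1)
            if v1 is not None:
                co[v1] = co.get(v1, 0) + (x2 - x1) + (x1 - x0)
            if v2 is not None:
                co[v2] = co.get(v2, 0) - (x1 - x0)
            leq(co, 0.0)
        # right piece through (t_m, g_m), grid[m+1:], (anchor, 1): concave
        right_pts = [(grid[m], m)] + [(grid[i], i) for i in range(m + 1, G)] + [
            (xs_full[-1], None)
        ]
        for j in range(len(right_pts) - 2):
            (x0, v0), (x1, v1), (x2, v2) = (
                right_pts[j],
                right_pts[j + 1],
                right_pts[j + 2],
            )
            co = {}
            b = 0.0
            if v0 is not None:
                co[v0] = co.get(v0, 0) + (x2 - x1)
            if v1 is not None:
                co[v1] = co.get(v1, 0) - (x2 - x1) - (x1 - x0)
            if v2 is not None:
                co[v2] = co.get(v2, 0) + (x1 - x0)
            else:
                b = -(x1 - x0)  # anchor value 1 moved to the rhs
            leq(co, b)
        # monotone across the grid (redundant with convexity+anchors, kept
        # for numerical safety)
        for i in range(G - 1):
            hi_, lo_ = (ia, i) if i + 1 == m else (i + 1, i)
            leq({lo_: 1, hi_: -1} if lo_ != hi_ else {lo_: 0}, 0.0)

        c = np.zeros(nv)
        c[id_] = 1.0
        res = linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=[(None, None)] * G + [(None, None), (0, None)],
            method="highs",
        )
        if res.status == 0 and res.fun < best:
            best = res.fun
    return max(float(best), 1.0 / (2 * n))


def gaussian_peak_area_numeric(sigma: float, fraction: float, grid: int = 4001) -> float:
    """Area where a circular Gaussian of s.d. sigma exceeds fraction*peak,
    by direct numeric integration on a fine grid."""
    half = 6 * sigma
    xs = np.linspace(-half, half, grid)
    dx = xs[1] - xs[0]
    xx, yy = np.meshgrid(xs, xs)
    z = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return float((z > fraction).sum() * dx * dx)
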