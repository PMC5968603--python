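"""Survey-weighted quantile regression.

Estimates conditional quantiles by minimising the weighted check loss

    sum_i  w_i * rho_tau(y_i - x_i' beta),    rho_tau(r) = r * (tau - 1{r < 0})

which for tau = 0.5 is weighted least-absolute-deviation (median) regression.
Survey weights multiply the loss, so the fit targets quantiles of the
*weighted* population the sample represents.

Two solvers are provided:

``"fn"`` (default)
    A Frisch-Newton primal-dual interior-point method on the bounded dual

        min y's   s.t.  X's = tau * X'w,   0 <= s <= w,

    followed by a vertex polish: the optimal basis interpolates p
    observations exactly, so the final coefficients are recovered to
    machine precision from a p x p linear solve. This is the algorithm
    family used by R's quantreg ``method = "fn"`` and is fast enough to sit
    inside bootstrap loops.

``"lp"``
    The same dual handed to scipy's HiGHS simplex, reading the coefficients
    off the equality-constraint marginals. Slower; kept as an internal
    cross-check and fallback.

In a saturated all-indicator design the minimiser of the weighted check
loss at tau = 0.5 is, generically, the per-group lower weighted median, so
the fitted group contrasts coincide with differences of weighted medians.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["fit_weighted_quantreg", "QuantregFit"]

_MAX_ITER = 100
_GAP_TOL = 1e-11


class QuantregFit:
    """Result of a weighted quantile-regression fit.

    Attributes
    ----------
    params : ndarray, shape (p,)
        Coefficients in the column order of the design matrix.
    tau : float
        Quantile level the fit targets.
    columns : list of str or None
        Optional column names, for prediction bookkeeping.
    """

    __slots__ = ("params", "tau", "columns")

    def __init__(self, params: np.ndarray, tau: float, columns=None):
        self.params = np.asarray(params, dtype=float)
        self.tau = tau
        self.columns = list(columns) if columns is not None else None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.params

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"QuantregFit(tau={self.tau}, params={np.round(self.params, 4)})"


def fit_weighted_quantreg(
    X,
    y,
    weights=None,
    tau: float = 0.5,
    columns=None,
    solver: str = "fn",
) -> QuantregFit:
    """Fit a weighted quantile regression.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Design matrix (include the intercept column explicitly).
    y : array-like, shape (n,)
        Response.
    weights : array-like, shape (n,), optional
        Positive survey weights; defaults to 1.
    tau : float
        Quantile in (0, 1); 0.5 gives median regression.
    columns : sequence of str, optional
        Names carried through to the fit object.
    solver : {"fn", "lp"}
        Interior-point Frisch-Newton (fast, default) or HiGHS simplex.

    Raises
    ------
    ValueError
        If the design is rank deficient (collinear terms), with the offending
        column named when names are supplied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per observation")
    if n < p:
        raise ValueError("need at least as many observations as parameters")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        culprit = _collinear_column(X, columns)
        raise ValueError(f"design matrix is rank deficient (collinear term: {culprit})")

    if solver == "lp":
        beta = _fit_lp(X, y, w, tau)
    elif solver == "fn":
        beta = _fit_fn(X, y, w, tau)
        beta = _polish(X, y, w, tau, beta)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return QuantregFit(beta, tau, columns)


def _fit_lp(X, y, w, tau):
    """Bounded dual via HiGHS; coefficients are the equality marginals."""
    n, p = X.shape
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(p),
        bounds=np.column_stack([-(1.0 - tau) * w, tau * w]),
        method="highs",
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    return -np.asarray(res.eqlin.marginals, dtype=float)


def _fit_fn(X, y, w, tau):
    """Frisch-Newton predictor-corrector on the bounded dual.

    Solves min y's s.t. X's = tau X'w, 0 <= s <= w.  The multiplier on the
    equality block is the coefficient vector.  Mehrotra corrector, step
    damping 0.9995, stop on small relative duality gap.
    """
    n, p = X.shape
    b = tau * (X.T @ w)

    # interior start
    s = tau * w.copy()
    t = w - s
    beta, *_ = np.linalg.lstsq(X * w[:, None] ** 0.5, y * w**0.5, rcond=None)
    r = y - X @ beta
    z = np.maximum(r, 0.0) + 1e-3 * np.std(y) + 1e-8
    u = np.maximum(-r, 0.0) + 1e-3 * np.std(y) + 1e-8

    scale = 1.0 + abs(float(y @ s))
    for _ in range(_MAX_ITER):
        mu = (s @ z + t @ u) / (2 * n)
        gap = s @ z + t @ u
        if gap < _GAP_TOL * scale:
            break
        if gap < 1e-2 * scale:
            # the active set is usually settled well before the duality gap
            # closes: try to jump to the vertex and certify it exactly
            cand = _certified_vertex(X, y, w, tau, beta)
            if cand is not None:
                return cand

        d = 1.0 / (z / s + u / t)  # diagonal of D
        r_dual = y - X @ beta - z + u
        r_prim = b - X.T @ s

        # affine-scaling (predictor) step
        rhs = r_prim + X.T @ (d * (r_dual + z - u))
        M = X.T @ (d[:, None] * X)
        try:
            L = np.linalg.cholesky(M)
            dbeta_aff = _chol_solve(L, rhs)
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular guard
            dbeta_aff = np.linalg.solve(M + 1e-12 * np.eye(p), rhs)
            L = None
        ds_aff = d * (X @ dbeta_aff - r_dual - z + u)
        dz_aff = -z - z / s * ds_aff
        du_aff = -u + u / t * ds_aff
        dt_aff = -ds_aff

        a_p = _max_step(s, ds_aff, t, dt_aff)
        a_d = _max_step(z, dz_aff, u, du_aff)
        mu_aff = ((s + a_p * ds_aff) @ (z + a_d * dz_aff) + (t + a_p * dt_aff) @ (u + a_d * du_aff)) / (2 * n)
        sigma = (mu_aff / mu) ** 3 if mu > 0 else 0.0

        # corrector
        cz = (sigma * mu - ds_aff * dz_aff) / s
        cu = (sigma * mu - dt_aff * du_aff) / t
        rhs = r_prim + X.T @ (d * (r_dual + z - u - cz + cu))
        if L is not None:
            dbeta = _chol_solve(L, rhs)
        else:  # pragma: no cover
            dbeta = np.linalg.solve(M + 1e-12 * np.eye(p), rhs)
        ds = d * (X @ dbeta - r_dual - z + u + cz - cu)
        dt_ = -ds
        dz = (sigma * mu - z * ds) / s - z + (-ds_aff * dz_aff) / s
        du = (sigma * mu - u * dt_) / t - u + (-dt_aff * du_aff) / t

        a_p = 0.9995 * _max_step(s, ds, t, dt_)
        a_d = 0.9995 * _max_step(z, dz, u, du)
        a = min(a_p, a_d, 1.0)
        s += a * ds
        t += a * dt_
        z += a * dz
        u += a * du
        beta += a * dbeta

    return beta


def _max_step(x1, dx1, x2, dx2):
    """Largest step in [0, 1] keeping x1 + a dx1 > 0 and x2 + a dx2 > 0."""
    a = 1.0
    for x, dx in ((x1, dx1), (x2, dx2)):
        neg = dx < 0
        if np.any(neg):
            a = min(a, float(np.min(-x[neg] / dx[neg])))
    return a


def _chol_solve(L, rhs):
    return np.linalg.solve(L.T, np.linalg.solve(L, rhs))


def _certified_vertex(X, y, w, tau, beta):
    """Snap to the vertex implied by ``beta`` and verify LP optimality.

    The p observations with the smallest absolute residuals form the trial
    basis B. Complementary slackness pins the dual variables of the
    non-basic observations at their box bounds (by residual sign); the
    basic duals then solve a p x p system and the vertex is optimal iff
    they land inside their box. Returns the exact coefficients on success,
    None otherwise.
    """
    n, p = X.shape
    r = y - X @ beta
    order = np.argpartition(np.abs(r), p - 1) if p < n else np.arange(n)
    basic = order[:p]
    XB = X[basic]
    try:
        cand = np.linalg.solve(XB, y[basic])
    except np.linalg.LinAlgError:
        return None
    r = y - X @ cand
    r[basic] = 0.0
    nonbasic = np.ones(n, dtype=bool)
    nonbasic[basic] = False
    d = np.where(r > 0, tau * w, -(1.0 - tau) * w)
    rhs = -X[nonbasic].T @ d[nonbasic]
    try:
        dB = np.linalg.solve(XB.T, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    slack = 1e-9 * (1.0 + w[basic])
    if np.all(dB >= -(1.0 - tau) * w[basic] - slack) and np.all(dB <= tau * w[basic] + slack):
        return cand
    return None


def _polish(X, y, w, tau, beta):
    """Snap an interior-point solution onto the optimal vertex.

    A basic solution of the quantile-regression LP interpolates p
    observations; we take the p smallest absolute residuals, solve the
    interpolation system exactly, and keep the result if it does not
    increase the weighted check loss. Degenerate bases fall back to the
    unpolished estimate.
    """
    n, p = X.shape
    r = y - X @ beta
    idx = np.argpartition(np.abs(r), min(p, n - 1))[:p]
    XB = X[idx]
    if np.linalg.matrix_rank(XB) < p:
        return beta
    try:
        cand = np.linalg.solve(XB, y[idx])
    except np.linalg.LinAlgError:  # pragma: no cover
        return beta
    if _check_loss(X, y, w, tau, cand) <= _check_loss(X, y, w, tau, beta) + 1e-9 * (1 + np.abs(y).max()):
        return cand
    return beta


def _check_loss(X, y, w, tau, beta):
    r = y - X @ beta
    return float(np.sum(w * r * (tau - (r < 0))))


def _collinear_column(X: np.ndarray, columns) -> str:
    """Name one column involved in a rank deficiency (best effort)."""
    p = X.shape[1]
    names = columns if columns is not None else [f"x{j}" for j in range(p)]
    kept: list[int] = []
    for j in range(p):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            return str(names[j])
        kept.append(j)
    return "unknown"
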