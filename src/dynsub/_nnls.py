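"""Non-negative least squares with block principal pivoting.

Solves min_X >= 0 ||C X - B||_F for many right-hand sides at once via the
normal equations, exchanging whole blocks of active/passive variables per
iteration (Kim & Park style) with the standard full-exchange -> backoff ->
single-variable safeguard that guarantees termination.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

__all__ = ["nnls_bpp"]


def _solve_groups(CtC, CtB, X, Y, F, cols):
    """Refresh X (passive part) and Y (active gradient) for given columns,
    grouping columns that share a passive-set pattern into one solve."""
    patterns: dict[bytes, list[int]] = {}
    for j in cols:
        patterns.setdefault(F[:, j].tobytes(), []).append(j)
    for key, js in patterns.items():
        f = np.frombuffer(key, dtype=bool)
        js = np.asarray(js)
        X[:, js] = 0.0
        if not f.any():
            Y[:, js] = -CtB[:, js]
            continue
        Kff = CtC[np.ix_(f, f)]
        rhs = CtB[np.ix_(f, js)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", linalg.LinAlgWarning)
                sol = linalg.solve(Kff, rhs, assume_a="pos")
        except (linalg.LinAlgError, ValueError):
            sol = np.linalg.lstsq(Kff, rhs, rcond=None)[0]
        X[np.ix_(f, js)] = sol
        g = ~f
        Y[:, js] = 0.0
        if g.any():
            Y[np.ix_(g, js)] = CtC[np.ix_(g, f)] @ sol - CtB[np.ix_(g, js)]


def nnls_bpp(CtC: np.ndarray, CtB: np.ndarray, tol: float = 1e-12,
             max_iter: int | None = None) -> np.ndarray:
    """Solve the NNLS normal-equation system C'C X = C'B with X >= 0.

    Parameters are the Gram matrix ``CtC`` (q x q) and cross-product
    ``CtB`` (q x r); one constrained solution column is returned per
    right-hand side.
    """
    CtC = np.asarray(CtC, dtype=float)
    CtB = np.asarray(CtB, dtype=float)
    if CtB.ndim == 1:
        return nnls_bpp(CtC, CtB[:, None], tol=tol, max_iter=max_iter)[:, 0]
    q, r = CtB.shape
    if CtC.shape != (q, q):
        raise ValueError("CtC and CtB shapes do not conform")
    if max_iter is None:
        max_iter = 5 * (q + 10)

    X = np.zeros((q, r))
    Y = -CtB.copy()
    F = np.zeros((q, r), dtype=bool)  # passive sets
    alpha = np.full(r, 3, dtype=int)
    beta = np.full(r, q + 1, dtype=int)

    _solve_groups(CtC, CtB, X, Y, F, np.arange(r))
    for _ in range(max_iter):
        infeasible = (F & (X < -tol)) | (~F & (Y < -tol))
        n_inf = infeasible.sum(axis=0)
        cols = np.where(n_inf > 0)[0]
        if cols.size == 0:
            break
        for j in cols:
            v = infeasible[:, j]
            if n_inf[j] < beta[j]:
                beta[j] = n_inf[j]
                alpha[j] = 3
            elif alpha[j] > 0:
                alpha[j] -= 1
            else:
                # exchange only the infeasible variable of largest index
                k = int(np.max(np.where(v)[0]))
                v = np.zeros(q, dtype=bool)
                v[k] = True
            F[v, j] = ~F[v, j]
        _solve_groups(CtC, CtB, X, Y, F, cols)
    else:
        warnings.warn("nnls_bpp reached its iteration cap; clipping solution",
                      stacklevel=2)
    np.maximum(X, 0.0, out=X)
    return X
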