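"""Shared statistical helpers: Spearman correlation and FDR adjustment."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

__all__ = ["spearman", "bh_adjust", "fisher_z"]

#: below this sample size the Spearman p-value is computed by exact
#: enumeration of all rank permutations instead of the t-approximation
EXACT_SPEARMAN_N = 10


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties are handled with the average-rank convention.  For fewer than
    ``EXACT_SPEARMAN_N`` observations the p-value is computed exactly by
    enumerating every permutation of one rank vector; otherwise the
    standard t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman expects two 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = np.std(rx)
    sy = np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < EXACT_SPEARMAN_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        # t-approximation, mirroring the large-sample behaviour of
        # scipy.stats.spearmanr
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(1.0, p)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fisher_z(r, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher r-to-Z transform, clipping |r| at ``clip`` to keep Z finite."""
    r = np.asarray(r, dtype=float)
    return np.arctanh(np.clip(r, -clip, clip))
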